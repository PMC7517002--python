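"""SVM-DT-ELM team-collaboration decision strategy.

The one-vs-one SVM is the main decider.  A test sample is *referred* to the
auxiliary classifiers when the SVM looks unreliable on it, which happens in
two cases:

a) the top vote count is tied between classes, or
b) the margin predicate on the absolute pairwise decision values holds:
   with ``u_min``/``h_max`` the smallest/largest |decision value| among the
   pairwise models involving the top-voted class and ``v_min``/``s_max`` the
   same for the runner-up class,

   ``u_min > v_min  and  h_max*u_min > s_max*v_min  and
   t1 < h_max*v_min  and  u_min*s_max < t2``

   with conditional parameters ``t1 = 1.5`` and ``t2 = 3.0`` by default.

Referred samples are arbitrated by three decision principles:

I.   Not referred: the SVM's top-voted class stands.
II.  Referred and the decision tree or the ELM agrees with the SVM's top
     class: majority rules, the top class stands.
III. Referred, neither auxiliary agrees with the top class, but one of them
     matches the SVM's second-ranked class: the second-ranked class wins.

If none applies (both auxiliaries disagree with both of the SVM's top two
classes) the verdict falls back to the SVM's top class, tagged FALLBACK.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifiers import (
    DtModel,
    ElmModel,
    PairwiseDecision,
    SvmModel,
    svm_decide,
)

__all__ = [
    "ReferralConfig",
    "MarginSummary",
    "TeamVerdict",
    "margin_summary",
    "margin_predicate",
    "is_referral",
    "team_decide",
    "classify_batch",
]


@dataclass(frozen=True)
class ReferralConfig:
    """Conditional parameters of the margin-based referral predicate."""

    t1: float = 1.5
    t2: float = 3.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError(f"t1 and t2 must be > 0, got {self.t1}, {self.t2}")


@dataclass(frozen=True)
class MarginSummary:
    """Extreme |decision values| of the models involving the SVM's top two
    classes; the raw material of the referral predicate."""

    u_min: float
    h_max: float
    v_min: float
    s_max: float


@dataclass(frozen=True)
class TeamVerdict:
    label: object
    principle: str  # "I" | "II" | "III" | "FALLBACK"
    referred: bool
    svm_top: object
    svm_second: object
    dt_label: object
    elm_label: object
    margins: MarginSummary


def margin_summary(pd: PairwiseDecision) -> MarginSummary:
    """Min/max |decision value| over models involving the top and second
    ranked classes (ranking already resolves vote ties by signed margin)."""
    top_vals = pd.values_involving(pd.top)
    second_vals = pd.values_involving(pd.second)
    return MarginSummary(
        u_min=min(top_vals),
        h_max=max(top_vals),
        v_min=min(second_vals),
        s_max=max(second_vals),
    )


def margin_predicate(m: MarginSummary, cfg: ReferralConfig | None = None) -> bool:
    """The four-part margin condition marking an SVM decision as unreliable."""
    cfg = cfg or ReferralConfig()
    return (
        m.u_min > m.v_min
        and m.h_max * m.u_min > m.s_max * m.v_min
        and cfg.t1 < m.h_max * m.v_min
        and m.u_min * m.s_max < cfg.t2
    )


def is_referral(pd: PairwiseDecision, cfg: ReferralConfig | None = None) -> bool:
    """Should this sample be re-diagnosed by the auxiliary classifiers?

    True when the top vote count is tied (condition a) or the four-part
    margin predicate holds (condition b); otherwise the SVM is trusted.
    """
    cfg = cfg or ReferralConfig()
    if pd.votes[pd.second] == pd.votes[pd.top]:  # condition a: tied top votes
        return True
    return margin_predicate(margin_summary(pd), cfg)


def team_decide(
    pd: PairwiseDecision,
    dt_label,
    elm_label,
    cfg: ReferralConfig | None = None,
) -> TeamVerdict:
    """Apply decision principles I-III (with fallback) to one sample."""
    cfg = cfg or ReferralConfig()
    for name, lbl in (("DT", dt_label), ("ELM", elm_label)):
        if lbl not in pd.classes:
            raise ValueError(f"{name} label {lbl!r} not among classes {pd.classes}")
    top, second = pd.top, pd.second
    margins = margin_summary(pd)
    referred = is_referral(pd, cfg)
    if not referred:
        label, principle = top, "I"
    elif dt_label == top or elm_label == top:
        label, principle = top, "II"
    elif dt_label == second or elm_label == second:
        label, principle = second, "III"
    else:
        label, principle = top, "FALLBACK"
    return TeamVerdict(
        label=label,
        principle=principle,
        referred=referred,
        svm_top=top,
        svm_second=second,
        dt_label=dt_label,
        elm_label=elm_label,
        margins=margins,
    )


def classify_batch(
    svm: SvmModel,
    dt: DtModel,
    elm: ElmModel,
    X,
    cfg: ReferralConfig | None = None,
) -> list[TeamVerdict]:
    """Team verdicts for every row of a feature matrix.

    All three models must share the feature space; the per-principle counts
    of the returned verdicts sum to the batch size.
    """
    cfg = cfg or ReferralConfig()
    X = np.asarray(X, float)
    if X.shape[1] != svm.estimator.n_features_in_:
        raise ValueError(
            f"feature dimension {X.shape[1]} != SVM's "
            f"{svm.estimator.n_features_in_}"
        )
    dt_labels = dt.predict(X)
    elm_labels = elm.predict(X)
    return [
        team_decide(svm_decide(svm, row), dt_lbl, elm_lbl, cfg)
        for row, dt_lbl, elm_lbl in zip(X, dt_labels, elm_labels)
    ]
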