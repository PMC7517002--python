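"""Train the three classifiers and watch the team strategy arbitrate.

The one-vs-one SVM decides directly for samples it classifies with a
confident full vote (principle I).  Samples whose vote pattern or decision
margins look unreliable are referred: if the decision tree or the ELM agrees
with the SVM's top class it stands (principle II); if instead one of them
matches the SVM's runner-up class, the runner-up wins (principle III).
"""

from collections import Counter

import emosig

# a compact 4-class dataset where classes differ in signal complexity
spec = emosig.demo_4class(n_per_class=10, duration_s=24.0)
recs = emosig.generate_dataset(spec, seed=5)
segs = [s for r in recs for s in emosig.segment_recording(r, 6.0)]
table = emosig.build_feature_table(segs)

cfg = emosig.ExperimentConfig(train_fraction=0.8, repetitions=1, seed=5)
train, test = emosig.holdout_split(table, cfg, 0)
scaler = emosig.Scaler().fit(train)
Xtr, ytr, _ = emosig.split_xy(scaler.transform(train))
Xte, yte, _ = emosig.split_xy(scaler.transform(test))

svm = emosig.train_svm(Xtr, ytr)
dt = emosig.train_dt(Xtr, ytr)
elm = emosig.train_elm(Xtr, ytr, M=min(10 * Xtr.shape[1], len(ytr)), seed=5)
print(f"SVM grid search selected C=2^{int(round(__import__('math').log2(svm.C)))}, "
      f"gamma=2^{int(round(__import__('math').log2(svm.gamma)))}")

# a permissive referral config so arbitration actually fires on this data
verdicts = emosig.classify_batch(svm, dt, elm, Xte, emosig.ReferralConfig(t1=0.5, t2=3.0))
acc = 100.0 * sum(v.label == y for v, y in zip(verdicts, yte)) / len(yte)
print(f"team accuracy on {len(yte)} held-out segments: {acc:.1f}%")
print("principle counts:", dict(Counter(v.principle for v in verdicts)))

referred = [v for v in verdicts if v.referred]
if referred:
    v = referred[0]
    print(f"\nfirst referred sample: SVM top={v.svm_top} (second={v.svm_second}), "
          f"DT={v.dt_label}, ELM={v.elm_label} -> {v.label} via principle {v.principle}")
    m = v.margins
    print(f"its margins: u_min={m.u_min:.2f} h_max={m.h_max:.2f} "
          f"v_min={m.v_min:.2f} s_max={m.s_max:.2f}")
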