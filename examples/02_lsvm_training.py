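"""Train the Lagrangian SVM on a balanced draw and classify held-out beats.

The LSVM solves the squared-slack SVM dual by a fixed-point iteration
(lambda^{k+1} = Q^{-1}(1 + (Q lambda^k - 1 - alpha lambda^k)_+)) instead
of quadratic programming; with the Gaussian kernel (gamma=10, chi=4) it
separates AF from sinus feature vectors.
"""

from afdetect import (
    LSVMConfig,
    SyntheticConfig,
    balanced_draw,
    evaluate,
    extract_features,
    gen_record,
    lsvm_train,
)

record = gen_record(SyntheticConfig(n_beats=3000, seed=7), signal_id="demo")
fm = extract_features(record)

# class-balanced training draw: half the minority class, matched equally
pool = type(record)("pool", record.rr_ms[10:-10], record.label[10:-10])
train_idx, test_idx = balanced_draw(pool, seed=7)
model = lsvm_train(fm.X[train_idx], fm.y[train_idx], LSVMConfig(gamma=10.0, chi=4.0))

print(f"training beats: {len(train_idx)} (balanced), "
      f"iterations: {model.iterations_run}, converged: {model.converged}")
pred = model.predict(fm.X[test_idx])
m = evaluate(pred, fm.y[test_idx])
print("held-out beat-level performance [%]:")
for k, v in m.round().items():
    print(f"  {k.upper():>4}: {v:6.2f}")
print("Se/Sp near 100 mean almost every held-out beat is assigned to the "
      "rhythm state that generated it.")
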