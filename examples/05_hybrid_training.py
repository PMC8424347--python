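"""Training the hybrid model on one split (reduced budget).

Generates a synthetic cohort, holds one sample out for validation and
one for early-stopping, trains the residual-encoder hybrid model for a
short budget, and compares the predicted material parameters and curves
of the held-out sample against its ground truth.  A full-protocol run
(1000 epochs, 10 restarts, all folds) uses the same calls with the
published TrainConfig defaults.
"""

import logging

import numpy as np

from artmech.hybridnet import hybrid_predict
from artmech.synthdata import CohortConfig, make_cohort
from artmech.trainer import Split, TrainConfig, train_with_restarts

logging.basicConfig(level=logging.WARNING)

config = CohortConfig(seed=1)
samples, truths = make_cohort(config)
ids = sorted(s.sample_id for s in samples)
validation, test = "s05", "s07"
split = Split(train_ids=tuple(i for i in ids if i not in (validation, test)),
              test_id=test, validation_id=validation)

tc = TrainConfig(epochs=60, restarts=2, master_seed=11)
best, states = train_with_restarts(
    samples, split, tc, fold_seed=11,
    validation_sample=next(s for s in samples if s.sample_id == validation))

print(f"restart validation R2: {[f'{s.validation_r2:.3f}' for s in states]}")
print(f"selected restart stopped at epoch {best.best_epoch} "
      f"(test R2 {best.best_test_r2:.3f})")

vs = next(s for s in samples if s.sample_id == validation)
pred = hybrid_predict(vs, best.network)
t = next(t for t in truths if t.sample_id == validation)
print(f"\nvalidation sample {validation}:")
print(f"  true params      c={t.c:6.2f}  k1={t.k1:6.2f}  k2={t.k2:6.2f}")
print(f"  predicted params c={pred.params.c:6.2f}  k1={pred.params.k1:6.2f}  "
      f"k2={pred.params.k2:6.2f}")
print(f"  curve R2 = {pred.fit.r2:.4f}")
print("\n(R2 compares the predicted stress-stretch curve against the "
      "sample's noisy observations; parameters can differ from truth "
      "where the curve constrains them weakly)")
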