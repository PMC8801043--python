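"""Learning-rate range test: which optimizer tolerates the largest step?

Sweeps learning rates over [1e-4, 1] for several optimizers on a small
corpus and reports the smoothed final loss per cell.  Adaptive-moment
methods (Adam/Adamax) typically remain stable at much larger learning
rates than SGD or RMSprop — which is why the default protocol trains with
Adamax at 0.015.
"""

import numpy as np

import scarnet as sn
from scarnet.surrogate import lr_range_test

corpus = sn.generate_corpus(120, master_seed=1, n_nodes=61, progress=True)
split = sn.split_and_scale(corpus, n_folds=5, seed=1)

table = lr_range_test(
    ["sgd", "rmsprop", "adam", "adamax"],
    np.logspace(-4, 0, 5),          # 1e-4 ... 1
    split.X_train, split.Y_train,
    epochs=30, batch_size=64, seed=1)

print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
best = table.iloc[0]
print(f"\nbest cell: {best.optimizer} at lr={best.lr:g} "
      f"(loss {best.loss:.2e}); divergent cells are flagged, not fatal")
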