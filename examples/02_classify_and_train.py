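"""From trawl catches to a trained abundance-class network.

Standardizes catches to CPUE (fish/1,000 m^2), averages within AHAs,
classifies the means onto the log-scale abundance classes, ranks the
habitat variables by PCA, and trains the single-hidden-layer network.
"""

import numpy as np

from chubsdm import (LakescapeConfig, NetConfig, generate_lakescape,
                     pca_rank, predict_class, relative_weights,
                     select_top_k, train)
from chubsdm.pipeline import build_training_table

config = LakescapeConfig(grid_rows=120, grid_cols=180, n_aha=150,
                         n_tows=1200, seed=3)
stack, zones, truth, samples = generate_lakescape(config)

table = build_training_table(stack, zones, samples)
print("abundance classes of the", len(table), "tow rows "
      "(class of each tow's AHA-mean CPUE):")
print(table["class"].value_counts().sort_index().to_string())

ranking = pca_rank(table[stack.names])
print(f"\nPCA: first two axes explain "
      f"{100 * ranking.variance_fractions[:2].sum():.1f}% of variance")
selected = select_top_k(ranking, 10)
print("selected variables (by vector length):", selected)

net = NetConfig(n_inputs=10, n_hidden=46, seed=3, max_epochs=5000)
model = train(table[selected], table["class"].to_numpy(), net)
pred = predict_class(model, table[selected])
acc = (pred == table["class"].to_numpy()).mean()
print(f"\nnetwork: stopped at epoch {model.best_epoch}, "
      f"4-class agreement with observed classes {acc:.1%}")
print("\nsigned connection-weight importances (top 5 by magnitude):")
rw = relative_weights(model)
print(rw.reindex(rw.abs().sort_values(ascending=False).index)[:5]
      .round(2).to_string())
print("positive = the variable raises predicted abundance")
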