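"""Build the marker graphs and inspect their normalized adjacency.

The classifier aggregates marker coordinates over a skeleton graph using
O_hat = T~^(-1/2) (O + I) T~^(-1/2). This script builds the two shipped
presets — the 39-marker body and the 46-marker body+racket — and prints
their basic structure.
"""

import numpy as np

from strokegcn import body_graph, body_racket_graph

body = body_graph()
full = body_racket_graph()

print(f"body graph: {body.n_nodes} nodes, "
      f"{int(body.O.sum() / 2)} anatomical edges")
print(f"body+racket graph: {full.n_nodes} nodes, "
      f"{int(full.O.sum() / 2)} edges "
      f"({int(full.O[39:, 39:].sum() / 2)} rigid racket edges = complete K7)")

degrees = full.O_tilde.sum(axis=1)
print(f"self-looped degrees range {int(degrees.min())}..{int(degrees.max())}")
print(f"O_hat symmetric: {np.allclose(full.O_hat, full.O_hat.T)}; "
      f"entries in [{full.O_hat.min():.3f}, {full.O_hat.max():.3f}]")
# Each O_hat row mixes a marker with its neighbours; entry (i,j) is
# 1/sqrt(d_i d_j) for connected pairs, so hubs are down-weighted.
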