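"""The with/without-racket comparison on known ground truth.

The generator controls where the class signal lives. With
racket_informative="both" the drive/volley distinction is carried by the
racket pose only, so stripping the racket channels must cost accuracy;
with "body_only" the racket moves independently of the class and the two
input conditions should be statistically indistinguishable.

Runtime: a few minutes on one CPU (20 training runs).
"""

from strokegcn.experiments import racket_ablation

result = racket_ablation(seed=11)
for mode, r in result.items():
    print(f"signal placement: {mode}")
    print(f"  mean accuracy with racket (46 nodes):    "
          f"{r['mean_accuracy_with_racket']:.1f}%")
    print(f"  mean accuracy without racket (39 nodes): "
          f"{r['mean_accuracy_without_racket']:.1f}%")
    print(f"  Welch t = {r['welch_t']:.2f}, p = {r['welch_p']:.3f} "
          f"over {r['runs']} runs per condition")
# Expected pattern: a clear accuracy gain from the racket channels when
# they carry signal, and no significant difference when they do not.
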