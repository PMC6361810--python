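"""Impute a dropout-ridden count matrix and inspect what changed.

Generates a small clustered dataset with known dropouts, runs the full
pipeline (normalize -> log -> nuclear-norm completion -> inverse
transforms), and reports how many zeros were filled and how well the
dropout positions were recovered.
"""

import numpy as np

from mcimpute import generate_scrnaseq, mcimpute, recovery_metrics
from mcimpute.preprocess import PreprocessConfig

truth, observed = generate_scrnaseq(m_cells=200, n_genes=150, seed=1)
print(f"cells x genes : {observed.shape}")
print(f"observed zeros: {(observed.values == 0).mean():.1%}")
print(f"true dropouts : {truth.dropout_positions.mask.mean():.1%} of entries")

out = mcimpute(observed, method="nnm", preprocess_cfg=PreprocessConfig(filter=False))
print(f"solver        : {out.result.method}, {out.result.iterations} iterations")

# dropout positions: how close are the imputed counts to the true counts?
met = recovery_metrics(truth.counts_true, out.counts, truth.dropout_positions)
baseline = recovery_metrics(truth.counts_true, observed, truth.dropout_positions)
print(f"NMSE at dropout positions: imputed {met.nmse:.3f} vs zero-filled {baseline.nmse:.3f}")
print(f"zeros after imputation   : {(out.counts.values < 0.5).mean():.1%}")

# An NMSE well below the zero-filled baseline's 1.0 means the completion
# reconstructed most of the lost expression rather than leaving holes.
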