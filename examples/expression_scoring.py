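"""Score a synthetic two-model cohort with the composite anti-TME signature.

Simulates counts for a cohort (two tumour models x control/treated arms x
three timepoints), applies the counts-per-million detection filter and the
log2-RPKM transform, then computes per-sample ssGSEA scores for each
component signature and their anti-TME union.  In the chemo-responsive
model A the treated arm carries a planted up-regulation of the signature,
which the score recovers.
"""

import numpy as np
import pandas as pd

from ecmstruct import cpm_filter, log_rpkm, score_collection
from ecmstruct.synthetic import (
    CohortGroundTruth, default_gene_universe, default_signatures,
    generate_cohort,
)

gt = CohortGroundTruth(signature_effect=2.0, seed=1)
counts, samples, _, _ = generate_cohort(gt, kind="counts")

kept = cpm_filter(counts)  # >= 1 cpm in >= 25% of samples
lengths = pd.Series(1000.0, index=kept.index)  # uniform synthetic lengths
expr = log_rpkm(kept, lengths)

sigs = default_signatures(default_gene_universe())
scores = score_collection(expr, sigs)

print(f"{counts.shape[0]} genes simulated, {kept.shape[0]} pass the cpm filter")
summary = scores.join(samples[["model", "arm"]]).groupby(["model", "arm"])[
    "anti_TME"].mean()
print("\nmean anti-TME score by model and arm:")
print(summary.round(3).to_string())
print("\nOnly treated model-A samples carry the planted signature shift, so"
      "\ntheir anti-TME score stands above every other group.")
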