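"""TPM normalization and the housekeeping-level expression flag.

Counts are divided by transcript length and rescaled to sum to one million;
an SM core gene is flagged expressed when its TPM reaches the weakest
housekeeping gene (tubulin, EF1, actin, ubiquitin in the real assay).
"""

import pandas as pd

from hgtcensus import sm_census as sm

counts = pd.Series(
    {"nrps_1": 820, "nrps_2": 0, "tc_1": 900, "tubulin": 900, "ef1": 2500, "other": 3000}
)
lengths = pd.Series(
    {"nrps_1": 5400, "nrps_2": 4800, "tc_1": 1100, "tubulin": 1500, "ef1": 1400, "other": 2000}
)
tpm = sm.tpm_normalize(counts, lengths)
print("TPM per gene (sums to 1e6):")
print(tpm.round(1).to_string())

ledger = [
    sm.SmCoreGene("nrps_1", "G", "NRPS"),
    sm.SmCoreGene("nrps_2", "G", "NRPS"),
    sm.SmCoreGene("tc_1", "G", "TC"),
]
report = sm.expression_report(tpm, ledger, housekeeping_ids=["tubulin", "ef1"])
print("\nexpression report (rank is within all genes):")
print(report.to_string(index=False))
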