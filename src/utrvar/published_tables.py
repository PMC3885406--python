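"""Curated candidate tables from an NSCLC UTR-variant screen.

Small plain-text tables bundled with the package: the structure-arm
candidates recorded in genes carrying more than one disruptive SNV, the
recurrently hit miRNAs of the target-site arm, and the target-site changes
involving NSCLC-associated miRNAs.  They serve as fixed reference inputs
for the recurrence statistics and the worked examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# published marginal counts of the same screen (gene universe, cancer-gene
# list size, disruptive-gene counts, screening-space dimensions)
N_GENES_TOTAL = 6462
N_CANCER_GENES = 1347
N_DISRUPTIVE_GENES = 803
N_DISRUPTIVE_CANCER_GENES = 188
N_SNVS_TOTAL = 29290
N_MATURE_MIRNAS = 2042


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("utrvar.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def structure_multi_snv_candidates() -> pd.DataFrame:
    """Structure-arm candidates in genes with more than one disruptive SNV
    (gene, mRNA, UTR, snv, p_value, measure, conserved overlap, dbSNP)."""
    return _load("nsclc_structure_multi_snv.tsv")


def recurrent_mirna_sites() -> pd.DataFrame:
    """Target-site changes of miRNAs with more than two changed targets."""
    return _load("nsclc_mirna_recurrent.tsv")


def nsclc_mirna_sites() -> pd.DataFrame:
    """Target-site changes involving NSCLC-associated miRNAs."""
    return _load("nsclc_specific_mirna_sites.tsv")
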