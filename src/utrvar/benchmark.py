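"""Truth-ledger scoring of the pipeline on synthetic cohorts.

These routines run the actual analysis stages against a generated dataset
and score them with the planted ground truth: sensitivity/specificity of
the structure arm, create/destroy/alter classification accuracy of the
target-site arm, null calibration of the empirical p-values, and the power
of the gene-level enrichment test at a planted odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import extract_window
from .mirna import run_mirna_pipeline
from .rna_folding import DEFAULT_MODEL, EnergyModel, compute_pair_probabilities
from .simulate import SyntheticDataset, simulate_enrichment_labels
from .structure import _mutate, scan_local_regions, structure_pvalues


@dataclass
class StructureRecovery:
    sensitivity: float  # stem-break SNVs with p_d < p_cutoff
    false_positive_rate: float  # neutral SNVs with p_d < p_cutoff
    n_positive: int
    n_negative: int


def evaluate_structure_recovery(
    dataset: SyntheticDataset,
    flank: int = 60,
    k_null: int = 49,
    p_cutoff: float = 0.1,
    model: EnergyModel = DEFAULT_MODEL,
    rng: np.random.Generator | int | None = None,
) -> StructureRecovery:
    """Score the structure arm on planted stem breaks vs neutral SNVs.

    The analysis window is scaled to the synthetic UTR geometry (the
    planted hairpins span < 40 nt, so a +/-60 window carries the whole
    element plus background).
    """
    rng = np.random.default_rng(rng)
    by_id = {t.transcript_id: t for t in dataset.transcripts}
    pos_p, neg_p = [], []
    for snv in dataset.snvs:
        label = dataset.truth_label(snv)
        if label not in ("stem_break", "neutral"):
            continue
        window = extract_window(snv, by_id[snv.transcript_id], flank)
        d_res, _ = structure_pvalues(window, model, k_null=k_null, rng=rng)
        (pos_p if label == "stem_break" else neg_p).append(d_res.p_value)
    return StructureRecovery(
        sensitivity=float(np.mean(np.asarray(pos_p) < p_cutoff)),
        false_positive_rate=float(np.mean(np.asarray(neg_p) < p_cutoff)),
        n_positive=len(pos_p),
        n_negative=len(neg_p),
    )


@dataclass
class SiteClassification:
    destroy_accuracy: float  # planted destroys classified destroy (pre-CLIP)
    create_accuracy: float
    alter_accuracy: float
    neutral_clean_rate: float  # neutral SNVs emitting no site change
    n_destroy: int
    n_create: int
    n_alter: int
    n_neutral: int


def evaluate_site_classification(
    dataset: SyntheticDataset, **pipeline_kwargs
) -> SiteClassification:
    """Score the pre-CLIP create/destroy/alter calls against the truth ledger."""
    res = run_mirna_pipeline(
        dataset.snvs,
        dataset.transcripts,
        dataset.mirnas,
        dataset.annotations,
        **pipeline_kwargs,
    )
    truth = dataset.ledger.truth
    calls: dict[tuple[str, str], set[str]] = {}
    for sc in res.all_changes:
        calls.setdefault((sc.snv.transcript_id, sc.snv.token), set()).add(sc.cls)

    def accuracy(label: str, want: str) -> tuple[float, int]:
        rows = truth[truth.label == label]
        hit = sum(
            want in calls.get((r.transcript_id, r.snv), set())
            for r in rows.itertuples(index=False)
        )
        return (hit / len(rows) if len(rows) else float("nan")), len(rows)

    d_acc, nd = accuracy("site_destroy", "destroy")
    c_acc, nc = accuracy("site_create", "create")
    a_acc, na = accuracy("site_alter", "alter")
    neutral = truth[truth.label == "neutral"]
    clean = sum(
        (r.transcript_id, r.snv) not in calls
        for r in neutral.itertuples(index=False)
    )
    return SiteClassification(
        destroy_accuracy=d_acc,
        create_accuracy=c_acc,
        alter_accuracy=a_acc,
        neutral_clean_rate=clean / len(neutral) if len(neutral) else float("nan"),
        n_destroy=nd,
        n_create=nc,
        n_alter=na,
        n_neutral=len(neutral),
    )


def null_pvalue_calibration(
    n_replicates: int = 200,
    k_null: int = 199,
    window_len: int = 61,
    gc: float = 0.5,
    model: EnergyModel = DEFAULT_MODEL,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, float]:
    """p-values of random substitutions scored against their own null.

    Each replicate draws a random window and a random single substitution,
    then ranks it among ``k_null`` null substitutions of the same window;
    under this exchangeable null the p-values are uniform.  Returns the
    p-value sample and its KS distance from U(0, 1).
    """
    rng = np.random.default_rng(rng)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    pvals = np.empty(n_replicates)
    alts = {b: [a for a in "ACGU" if a != b] for b in "ACGU"}
    for rep in range(n_replicates):
        wt = "".join(rng.choice(list("ACGU"), size=window_len, p=p))
        bpm_wt = compute_pair_probabilities(wt, model)
        pos = int(rng.integers(1, window_len + 1))
        alt = alts[wt[pos - 1]][int(rng.integers(3))]
        obs_bpm = compute_pair_probabilities(_mutate(wt, pos, alt), model)
        d_obs, _, _, _ = scan_local_regions(bpm_wt, obs_bpm)
        null_d = np.empty(k_null)
        for t in range(k_null):
            npos = int(rng.integers(1, window_len + 1))
            nalt = alts[wt[npos - 1]][int(rng.integers(3))]
            bpm_null = compute_pair_probabilities(_mutate(wt, npos, nalt), model)
            nd, _, _, _ = scan_local_regions(bpm_wt, bpm_null)
            null_d[t] = nd
        pvals[rep] = (1 + int(np.sum(null_d >= d_obs))) / (k_null + 1)
    ks = stats.kstest(pvals, "uniform")
    return pvals, float(ks.statistic)


def enrichment_power(
    odds_ratio: float,
    n_genes: int = 500,
    n_seeds: int = 50,
    disruptive_fraction: float = 0.124,
    cancer_fraction: float = 0.2,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Gene-level enrichment p-values over repeated label simulations."""
    rng = np.random.default_rng(rng)
    return np.array(
        [
            simulate_enrichment_labels(
                n_genes=n_genes,
                disruptive_fraction=disruptive_fraction,
                cancer_fraction=cancer_fraction,
                odds_ratio=odds_ratio,
                rng=rng,
            ).p_one_sided
            for _ in range(n_seeds)
        ]
    )
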