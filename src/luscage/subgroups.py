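"""Signature-defined patient subgroups and single-sample GSEA projection.

Patients are split into four subgroups by whether their exposures to two
chosen signatures (defective-MMR signatures SI6 and SI26 in the motivating
analysis) lie above or below the cohort mean of each. The two discordant
subgroups (high/low and low/high) isolate cohorts dominated by one of the two
mutational processes and are compared on clinical and molecular features.

Gene-level alteration matrices (non-silent SNP counts, |thresholded CNV|,
|methylation z|) are projected onto gene-set collections with single-sample
GSEA: per patient, genes are ranked by alteration value and the enrichment
score accumulates the gap between the weighted in-set and unweighted
out-of-set empirical distribution functions, with rank weight |r|^alpha
(alpha = 0.25 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .loads import SeverityMap
from .maf import MutationRecord
from .stats import bh_fdr, fisher_exact, spearman_test, wilcoxon_rank_sum

__all__ = [
    "classify_signature_subgroups",
    "characterize_subgroups",
    "read_gmt",
    "write_gmt",
    "GeneSetCollection",
    "gene_level_matrices",
    "ssgsea_score",
    "ssgsea_scores_for_patient",
    "project_pathways",
    "pathway_subgroup_tests",
    "pathway_age_correlation",
]


def classify_signature_subgroups(
    exposures: pd.DataFrame,
    sig_a: str = "SI6",
    sig_b: str = "SI26",
) -> pd.DataFrame:
    """Four-way subgrouping by cohort-mean thresholds on two exposures.

    A patient is 'high' for a signature iff their exposure is strictly above
    the cohort arithmetic mean of that exposure (raw scale); ties go to 'low'.
    Returns a DataFrame indexed by patient with columns ``{sig_a}_class``,
    ``{sig_b}_class`` and ``label`` (e.g. "high-SI6/low-SI26").
    """
    if len(exposures) < 2:
        raise ValueError("subgrouping needs at least 2 patients")
    for sig in (sig_a, sig_b):
        if sig not in exposures.columns:
            raise ValueError(f"signature {sig!r} not in exposure table")
    mean_a = exposures[sig_a].mean()
    mean_b = exposures[sig_b].mean()
    cls_a = np.where(exposures[sig_a] > mean_a, "high", "low")
    cls_b = np.where(exposures[sig_b] > mean_b, "high", "low")
    label = [f"{a}-{sig_a}/{b}-{sig_b}" for a, b in zip(cls_a, cls_b)]
    return pd.DataFrame(
        {f"{sig_a}_class": cls_a, f"{sig_b}_class": cls_b, "label": label},
        index=exposures.index,
    )


def characterize_subgroups(
    labels: pd.Series,
    group_a: str,
    group_b: str,
    continuous: pd.DataFrame | None = None,
    categorical: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Compare two subgroups on clinical/molecular features.

    Continuous variables (age, loads, …) are compared with the Wilcoxon
    rank-sum test; categorical ones (gender, smoking indicator, per-gene
    mutated/wild-type) with Fisher's exact test on the 2×k table collapsed to
    2×2 per level when k > 2 would be needed — here levels beyond binary are
    tested as level-vs-rest. BH-FDR is applied across all rows of the table.
    """
    labels = pd.Series(labels)
    in_a = labels.index[labels == group_a]
    in_b = labels.index[labels == group_b]
    if in_a.empty or in_b.empty:
        raise ValueError(f"empty subgroup: {group_a if in_a.empty else group_b}")
    rows = []
    if continuous is not None:
        for col in continuous.columns:
            a = continuous.loc[continuous.index.intersection(in_a), col].dropna()
            b = continuous.loc[continuous.index.intersection(in_b), col].dropna()
            if a.empty or b.empty:
                rows.append((col, "wilcoxon", len(a), len(b), np.nan, "empty-arm"))
                continue
            _, p = wilcoxon_rank_sum(a, b)
            rows.append((col, "wilcoxon", len(a), len(b), p, ""))
    if categorical is not None:
        for col in categorical.columns:
            series = categorical[col]
            a = series.loc[series.index.intersection(in_a)].dropna()
            b = series.loc[series.index.intersection(in_b)].dropna()
            levels = pd.unique(pd.concat([a, b]))
            if len(levels) < 2:
                rows.append((col, "fisher", len(a), len(b), 1.0, "single-level"))
                continue
            for level in levels if len(levels) > 2 else levels[:1]:
                table = [
                    [int((a == level).sum()), int((a != level).sum())],
                    [int((b == level).sum()), int((b != level).sum())],
                ]
                name = col if len(levels) == 2 else f"{col}={level}"
                rows.append((name, "fisher", len(a), len(b), fisher_exact(table), ""))
    out = pd.DataFrame(
        rows, columns=["variable", "test", f"n_{group_a}", f"n_{group_b}", "p_value", "flag"]
    ).set_index("variable")
    out["q_value"] = bh_fdr(out["p_value"].where(out["flag"] == ""))
    return out


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets (GMT content); duplicates within a set are collapsed."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self):
        cleaned = {}
        for name, genes in self.sets.items():
            uniq = list(dict.fromkeys(genes))
            if not uniq:
                raise ValueError(f"empty gene set: {name!r}")
            cleaned[name] = uniq
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one set per line, name TAB description TAB genes…."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, _desc, *genes = parts
            sets[name] = [g for g in genes if g]
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# gene-level alteration matrices
# ---------------------------------------------------------------------------

def gene_level_matrices(
    records: list[MutationRecord],
    cnv_matrix: pd.DataFrame | None = None,
    methylation_matrix: pd.DataFrame | None = None,
    severity: SeverityMap | None = None,
    gene_universe: list[str] | None = None,
    patients: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Build the per-layer gene×patient alteration matrices for ssGSEA.

    SNP layer: count of non-silent mutations (severity moderate/severe) per
    gene per patient, over all genes seen in the filtered records (or the
    supplied ``gene_universe``/``patients`` roster). CNV layer: |thresholded
    value|. Methylation layer: |z| after per-gene standardization. Gene
    universes are layer-specific (no forced harmonization).
    """
    severity = severity or SeverityMap()
    out: dict[str, pd.DataFrame] = {}
    genes = sorted({r.gene for r in records}) if gene_universe is None else list(gene_universe)
    if patients is None:
        patients = sorted({r.patient_id for r in records})
    gene_pos = {g: i for i, g in enumerate(genes)}
    pat_pos = {p: j for j, p in enumerate(patients)}
    counts = np.zeros((len(genes), len(patients)), dtype=int)
    for r in records:
        if severity.is_disruptive(r.variant_classification):
            gi, pj = gene_pos.get(r.gene), pat_pos.get(r.patient_id)
            if gi is not None and pj is not None:
                counts[gi, pj] += 1
    out["SNP"] = pd.DataFrame(counts, index=genes, columns=patients)
    if cnv_matrix is not None:
        out["CNV"] = cnv_matrix.abs()
    if methylation_matrix is not None:
        values = methylation_matrix.to_numpy(dtype=float)
        mean = np.nanmean(values, axis=1, keepdims=True)
        sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
        keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
        z = np.abs((values[keep] - mean[keep]) / sd[keep])
        out["methylation"] = pd.DataFrame(
            z, index=methylation_matrix.index[keep], columns=methylation_matrix.columns
        )
    return out


# ---------------------------------------------------------------------------
# ssGSEA
# ---------------------------------------------------------------------------

class DegenerateGeneSet(ValueError):
    """Gene set leaves no out-of-set (or no in-set) genes in the profile."""


def _rank_order(values: pd.Series) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Descending order of genes with mid-rank weights; ties broken by name.

    Returns (order, midranks, gene_names) where midranks[i] is the ascending
    mid-rank of the gene at descending position i (top gene ~ n).
    """
    names = np.asarray(values.index.astype(str))
    vals = values.to_numpy(dtype=float)
    order = np.lexsort((names, -vals))
    midranks = sps.rankdata(vals)[order]
    return order, midranks, list(names[order])


def ssgsea_score(values: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample GSEA enrichment score of one gene set for one patient.

    Genes are ranked by value descending (ties get mid-rank weights, tie order
    fixed by gene name); the score is the sum over ranked positions of
    P_in(i) − P_out(i), with P_in the running sum of |midrank|^alpha over
    in-set genes normalized by the in-set total, and P_out the running count
    of out-of-set genes normalized by their total.
    """
    if len(values) < 2:
        raise ValueError("need at least 2 profiled genes")
    in_set = set(gene_set)
    hit = np.array([g in in_set for g in values.index.astype(str)])
    if not hit.any():
        raise DegenerateGeneSet("gene set is disjoint from the profile")
    if hit.all():
        raise DegenerateGeneSet("gene set covers the whole profile; no out-of-set mass")
    order, midranks, _ = _rank_order(values)
    hit_ord = hit[order]
    weights = np.where(hit_ord, np.abs(midranks) ** alpha, 0.0)
    p_in = np.cumsum(weights) / weights.sum()
    misses = (~hit_ord).astype(float)
    p_out = np.cumsum(misses) / misses.sum()
    return float(np.sum(p_in - p_out))


def ssgsea_scores_for_patient(
    values: pd.Series, collection: GeneSetCollection, alpha: float = 0.25
) -> pd.Series:
    """Scores of every set in the collection for one patient (shared ranking).

    Sets disjoint from the profile (or covering it entirely) get NaN.
    """
    order, midranks, ordered_names = _rank_order(values)
    weights_all = np.abs(midranks) ** alpha
    name_pos = {g: i for i, g in enumerate(ordered_names)}
    n = len(ordered_names)
    out = {}
    for set_name, genes in collection:
        pos = [name_pos[g] for g in genes if g in name_pos]
        if not pos or len(pos) == n:
            out[set_name] = np.nan
            continue
        hit = np.zeros(n, dtype=bool)
        hit[pos] = True
        w = np.where(hit, weights_all, 0.0)
        p_in = np.cumsum(w) / w.sum()
        misses = (~hit).astype(float)
        p_out = np.cumsum(misses) / misses.sum()
        out[set_name] = float(np.sum(p_in - p_out))
    return pd.Series(out, name=values.name)


def project_pathways(
    matrices: dict[str, pd.DataFrame],
    gene_sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> dict[str, pd.DataFrame]:
    """ssGSEA score matrices (gene_set×patient), one per alteration layer.

    ``normalize=True`` divides each layer's scores by the overall score range
    (max − min over the whole layer), the cross-set normalization offered by
    the standard projection tool; off by default for single-dataset use.
    """
    out: dict[str, pd.DataFrame] = {}
    for layer, matrix in matrices.items():
        cols = {
            patient: ssgsea_scores_for_patient(matrix[patient], gene_sets, alpha)
            for patient in matrix.columns
        }
        scores = pd.DataFrame(cols)
        scores.index.name = "gene_set"
        if normalize:
            rng = np.nanmax(scores.to_numpy()) - np.nanmin(scores.to_numpy())
            if rng > 0:
                scores = scores / rng
        out[layer] = scores
    return out


def pathway_subgroup_tests(
    scores: pd.DataFrame, labels: pd.Series, group_a: str, group_b: str
) -> pd.DataFrame:
    """Wilcoxon of each pathway's scores between two subgroups, BH across sets."""
    in_a = labels.index[labels == group_a].intersection(scores.columns)
    in_b = labels.index[labels == group_b].intersection(scores.columns)
    if in_a.empty or in_b.empty:
        raise ValueError("a subgroup has no scored patients")
    rows = []
    for set_name in scores.index:
        a = scores.loc[set_name, in_a].dropna()
        b = scores.loc[set_name, in_b].dropna()
        if a.empty or b.empty:
            rows.append((set_name, len(a), len(b), np.nan, np.nan, "empty"))
            continue
        stat, p = wilcoxon_rank_sum(a, b)
        rows.append((set_name, len(a), len(b), stat, p, ""))
    out = pd.DataFrame(
        rows, columns=["gene_set", f"n_{group_a}", f"n_{group_b}", "statistic", "p_value", "flag"]
    ).set_index("gene_set")
    out["q_value"] = bh_fdr(out["p_value"])
    return out


def pathway_age_correlation(
    scores: pd.DataFrame, ages: pd.Series, B: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Spearman of each pathway score vs age, BH across sets."""
    common = scores.columns.intersection(ages.index)
    rows = []
    for k, set_name in enumerate(scores.index):
        res = spearman_test(
            scores.loc[set_name, common], ages.loc[common], variable=str(set_name),
            B=B, seed=None if seed is None else seed + k,
        )
        rows.append(res.to_dict())
    out = pd.DataFrame(rows).set_index("variable")
    out.index.name = "gene_set"
    out["q_value"] = bh_fdr(out["p_value"])
    return out
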