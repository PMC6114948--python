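"""Per-patient alteration burden statistics.

Four burdens are computed per patient: the global SNP load (filtered record
count), the number of distinct genes carrying at least one moderate/severe
mutation, the copy-number load (sum of |thresholded GISTIC value| over genes),
and the methylation-change rate (sum over genes of |z| after per-gene
standardization of beta values across the cohort).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .maf import MutationRecord

__all__ = [
    "SeverityMap",
    "DEFAULT_SEVERITY",
    "snp_load",
    "disrupted_gene_count",
    "cnv_load",
    "methylation_change_rate",
    "patient_loads",
]

#: default classification → severity mapping (configurable; see SeverityMap)
DEFAULT_SEVERITY: dict[str, str] = {
    "Nonsense_Mutation": "severe",
    "Frame_Shift_Del": "severe",
    "Frame_Shift_Ins": "severe",
    "Splice_Site": "severe",
    "Nonstop_Mutation": "severe",
    "Translation_Start_Site": "severe",
    "Missense_Mutation": "moderate",
    "In_Frame_Del": "moderate",
    "In_Frame_Ins": "moderate",
    "Silent": "low",
    "3'UTR": "low",
    "5'UTR": "low",
    "3'Flank": "low",
    "5'Flank": "low",
    "Intron": "low",
    "RNA": "low",
    "IGR": "low",
    "De_novo_Start_InFrame": "low",
    "De_novo_Start_OutOfFrame": "low",
}

_LEVELS = ("low", "moderate", "severe")


@dataclass
class SeverityMap:
    """Maps MAF variant classifications to {low, moderate, severe}.

    ``unknown_policy`` controls classifications absent from the mapping:
    'error' (default) raises; 'low' treats them as non-disruptive.
    """

    mapping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SEVERITY))
    unknown_policy: str = "error"

    def __post_init__(self):
        bad = {k: v for k, v in self.mapping.items() if v not in _LEVELS}
        if bad:
            raise ValueError(f"invalid severity level(s): {bad}")
        if self.unknown_policy not in ("error", "low"):
            raise ValueError(f"unknown_policy must be 'error' or 'low', got {self.unknown_policy!r}")

    def classify(self, variant_classification: str) -> str:
        try:
            return self.mapping[variant_classification]
        except KeyError:
            if self.unknown_policy == "low":
                return "low"
            raise ValueError(
                f"unmapped variant classification {variant_classification!r}"
            ) from None

    def is_disruptive(self, variant_classification: str) -> bool:
        return self.classify(variant_classification) in ("moderate", "severe")

    @classmethod
    def from_yaml(cls, path) -> "SeverityMap":
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(mapping=cfg.get("mapping", cfg), unknown_policy=cfg.get("unknown_policy", "error"))


def snp_load(records: list[MutationRecord]) -> pd.Series:
    """Number of retained mutation records per patient (patients present only)."""
    counts: dict[str, int] = {}
    for r in records:
        counts[r.patient_id] = counts.get(r.patient_id, 0) + 1
    return pd.Series(counts, dtype=int, name="snp_load").sort_index()


def disrupted_gene_count(
    records: list[MutationRecord], severity: SeverityMap | None = None
) -> pd.Series:
    """Distinct genes per patient with ≥1 moderate-or-severe mutation."""
    severity = severity or SeverityMap()
    genes: dict[str, set[str]] = {}
    for r in records:
        genes.setdefault(r.patient_id, set())
        if severity.is_disruptive(r.variant_classification):
            genes[r.patient_id].add(r.gene)
    return pd.Series(
        {p: len(g) for p, g in genes.items()}, dtype=int, name="disrupted_gene_count"
    ).sort_index()


def cnv_load(cnv_matrix: pd.DataFrame) -> pd.Series:
    """Per-patient sum of |thresholded copy-number value| over genes.

    Input is a gene×patient matrix of GISTIC-style thresholded calls in
    {-2,-1,0,1,2}; NaN entries are skipped. Out-of-range values raise, since
    they indicate a non-thresholded (wrong-level) input.
    """
    values = cnv_matrix.to_numpy(dtype=float)
    finite = values[np.isfinite(values)]
    if not np.all(np.isin(finite, (-2.0, -1.0, 0.0, 1.0, 2.0))):
        bad = np.unique(finite[~np.isin(finite, (-2.0, -1.0, 0.0, 1.0, 2.0))])
        raise ValueError(f"CNV matrix contains non-thresholded value(s): {bad[:5]}")
    load = np.nansum(np.abs(values), axis=0)
    return pd.Series(load, index=cnv_matrix.columns, name="cnv_load")


def methylation_change_rate(
    beta_matrix: pd.DataFrame,
    mode: str = "absolute",
) -> pd.Series:
    """Per-patient methylation-change rate from a gene×patient beta matrix.

    Each gene row is standardized across patients (mean 0, unit sample
    variance); the rate is the per-patient sum over genes of |z| (default) or
    of signed z (``mode='signed'``). Zero-variance genes are dropped with a
    warning; fewer than 3 patients is an error. NaN betas are skipped both in
    the standardization and the sum.
    """
    if mode not in ("absolute", "signed"):
        raise ValueError(f"mode must be 'absolute' or 'signed', got {mode!r}")
    if beta_matrix.shape[1] < 3:
        raise ValueError("methylation matrix needs >= 3 patients")
    values = beta_matrix.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean = np.nanmean(values, axis=1, keepdims=True)
        sd = np.nanstd(values, axis=1, ddof=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance or all-missing gene(s)",
            stacklevel=2,
        )
    z = (values[keep] - mean[keep]) / sd[keep]
    contrib = np.abs(z) if mode == "absolute" else z
    rate = np.nansum(contrib, axis=0)
    return pd.Series(rate, index=beta_matrix.columns, name="methylation_change_rate")


def patient_loads(
    records: list[MutationRecord],
    clinical: pd.DataFrame | None = None,
    cnv_matrix: pd.DataFrame | None = None,
    beta_matrix: pd.DataFrame | None = None,
    severity: SeverityMap | None = None,
) -> pd.DataFrame:
    """Assemble the per-patient load table, zero-filled on the clinical roster.

    ``clinical`` (indexed by patient_id) defines the roster when given;
    otherwise the union of patients seen in the inputs is used. SNP-derived
    columns are zero-filled for roster patients without records; CNV and
    methylation columns are NaN for patients absent from those matrices.
    """
    parts = [snp_load(records), disrupted_gene_count(records, severity)]
    if cnv_matrix is not None:
        parts.append(cnv_load(cnv_matrix))
    if beta_matrix is not None:
        parts.append(methylation_change_rate(beta_matrix))
    table = pd.concat(parts, axis=1)
    if clinical is not None:
        table = table.reindex(clinical.index)
        table = clinical.join(table)
    for col in ("snp_load", "disrupted_gene_count"):
        table[col] = table[col].fillna(0).astype(int)
    table.index.name = "patient_id"
    return table
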