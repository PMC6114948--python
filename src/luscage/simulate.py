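"""Synthetic LUSC-like cohorts with known ground truth.

Every pipeline stage can be exercised without external downloads: the
generator emits a clinical roster, a MAF-like mutation table whose
trinucleotide channels are drawn multinomially from known signature mixtures,
copy-number and methylation matrices with injected age trends, and toy GMT
gene-set files. Ground truth (per-patient exposure fractions, mutation
counts, coupling targets) is archived so recovery tests never re-simulate.

Age coupling uses a Gaussian copula: ages are the probability transform of a
latent normal score, and each coupled quantity shares a latent correlation
r = 2·sin(π·rho_target/6) with that score, which targets a chosen Spearman
rho directly.

The default configuration is the cohort the pipeline is meant to emulate:
~300 patients aged 40–85, log-normal mutation counts with a median of ~300
per patient, a smoking-dominated signature mixture, duplicate/ambiguous/
repeat-context record fractions matching the removal rates seen in real
TCGA-LUSC mutation tables (≈25%, ≈0.1%, ≈9%), and opposite-sign age coupling
(rho ∓0.3) for the two defective-MMR signatures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .maf import repeat_context_pass
from .profiles import BASES, CHANNELS_96, SUBSTITUTIONS
from .signatures import SignatureCatalog
from .subgroups import GeneSetCollection, write_gmt

__all__ = [
    "SimulationConfig",
    "make_synthetic_catalog",
    "simulate_cohort",
    "simulate_maf",
    "simulate_matrices",
    "simulate_gene_sets",
    "simulate_dataset",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_SMOKING_LEVELS = (
    "Lifelong non-smoker",
    "Current smoker",
    "Current reformed smoker >15yrs",
    "Current reformed smoker <=15yrs",
    "Current reformed smoker, duration unspecified",
)
_SMOKING_PROBS = (0.04, 0.28, 0.17, 0.50, 0.01)
_STAGE_LEVELS = ("1", "2", "3", "4")
_STAGE_PROBS = (0.49, 0.32, 0.17, 0.02)
_TRANSVERSION_PROBS = {"high": 0.82, "low": 0.18}


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    Fractions are per-record probabilities: ``duplicate_fraction`` is the
    share of the final MAF that consists of same-patient duplicate rows,
    ``multigene_fraction``/``repeat_context_fraction`` the share of records
    annotated to two genes / given a threshold-failing context.
    ``age_rho_targets`` maps signature labels to the Spearman rho their true
    exposure fraction should attain against age.
    """

    n_patients: int = 300
    age_range: tuple[float, float] = (40.0, 85.0)
    mutation_count_meanlog: float = math.log(300.0)
    mutation_count_sdlog: float = 0.6
    active_signatures: tuple[tuple[str, float], ...] = (
        ("SI4", 0.40), ("SI1", 0.20), ("SI6", 0.15), ("SI5", 0.15), ("SI26", 0.10),
    )
    age_rho_targets: dict[str, float] = field(
        default_factory=lambda: {"SI6": -0.3, "SI26": 0.3}
    )
    exposure_sdlog: float = 0.5  # per-patient log-normal jitter of mixture weights
    duplicate_fraction: float = 0.25
    multigene_fraction: float = 0.001
    repeat_context_fraction: float = 0.09
    silent_fraction: float = 0.25
    indel_fraction: float = 0.05
    n_genes: int = 300
    n_cnv_genes: int = 200
    cnv_event_rate: float = 0.05
    cnv_age_rho: float = 0.0
    n_methylation_genes: int = 200
    methylation_age_rho: float = -0.3
    seed: int = 17

    def validate(self) -> None:
        problems = []
        if self.n_patients < 2:
            problems.append("n_patients must be >= 2")
        if not self.age_range[0] < self.age_range[1]:
            problems.append("age_range must be increasing")
        total = sum(f for _, f in self.active_signatures)
        if abs(total - 1.0) > 1e-8:
            problems.append(f"active signature base fractions sum to {total}, not 1")
        for sig, rho in self.age_rho_targets.items():
            if not abs(rho) < 1.0:
                problems.append(f"|age rho target| for {sig} must be < 1")
        for name in ("duplicate_fraction", "multigene_fraction", "repeat_context_fraction",
                     "silent_fraction", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0, 1], got {v}")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))

    @property
    def gene_universe(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(1, self.n_genes + 1)]


# ---------------------------------------------------------------------------
# synthetic signature catalog
# ---------------------------------------------------------------------------

def make_synthetic_catalog(n_signatures: int = 30, seed: int = 0) -> SignatureCatalog:
    """A synthetic stand-in for the COSMIC v2 signature catalog.

    Same shape and contract as the real catalog (96 canonical channels × SI1…
    SI30, column-stochastic) but with synthetic probabilities: sparse
    Dirichlet columns, with structured spectra for the signatures the
    age analysis leans on — SI1 (C>T at NpCpG), SI4 (broad C>A), SI6 (C>T at
    NpCpG with a distinct flank profile plus C>A mass) and SI26 (broad T>C).
    Deterministic in ``seed``; this is NOT the published COSMIC catalog.
    """
    rng = np.random.default_rng(seed)
    labels = tuple(f"SI{i}" for i in range(1, n_signatures + 1))
    cols = []
    channel_sub = [c[2:5] for c in CHANNELS_96]  # substitution of each channel
    channel_three = [c[6] for c in CHANNELS_96]
    for label in labels:
        base = rng.dirichlet(np.full(96, 0.08))  # sparse COSMIC-like background
        boost = np.zeros(96)
        if label == "SI1":
            boost[[i for i in range(96) if channel_sub[i] == "C>T" and channel_three[i] == "G"]] = 1.0
        elif label == "SI4":
            boost[[i for i in range(96) if channel_sub[i] == "C>A"]] = 0.8
        elif label == "SI6":
            idx = [i for i in range(96) if channel_sub[i] == "C>T" and channel_three[i] == "G"]
            boost[idx] = rng.permuted(np.linspace(0.2, 1.0, len(idx)))
            boost[[i for i in range(96) if channel_sub[i] == "C>A" and channel_three[i] == "T"]] = 0.5
        elif label == "SI26":
            boost[[i for i in range(96) if channel_sub[i] == "T>C"]] = 0.8
        elif label == "SI5":
            boost[:] = 0.15  # flat, clock-like
        if boost.any():
            # distinctive within-peak flank tilt, as real signatures have
            tilt = rng.lognormal(0.0, 0.35, size=96)
            structured = boost * tilt
            structured /= structured.sum()
            col = 0.10 * base + 0.90 * structured
        else:
            col = base
        cols.append(col / col.sum())
    return SignatureCatalog(
        matrix=np.column_stack(cols), channel_labels=CHANNELS_96, signature_labels=labels
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _latent_corr(rho_s: float) -> float:
    """Gaussian-copula latent Pearson correlation hitting Spearman rho_s."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Clinical roster plus archived ground truth.

    Ages are uniform on ``age_range`` (probability transform of a latent
    normal score); per-patient exposure fractions jitter the base mixture
    log-normally, with coupled signatures sharing a latent correlation with
    the age score. Deterministic under ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    patients = [f"TCGA-SY-{i:04d}" for i in range(1, n + 1)]

    z_age = rng.standard_normal(n)
    lo, hi = config.age_range
    ages = lo + (hi - lo) * sps.norm.cdf(z_age)

    sig_names = [s for s, _ in config.active_signatures]
    base = np.array([f for _, f in config.active_signatures])
    weights = np.empty((n, len(sig_names)))
    for j, sig in enumerate(sig_names):
        rho_t = config.age_rho_targets.get(sig, 0.0)
        r = _latent_corr(rho_t)
        z = r * z_age + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
        weights[:, j] = base[j] * np.exp(config.exposure_sdlog * z)
    fractions = weights / weights.sum(axis=1, keepdims=True)

    n_mutations = np.maximum(
        1,
        np.round(
            rng.lognormal(config.mutation_count_meanlog, config.mutation_count_sdlog, n)
        ).astype(int),
    )

    clinical = pd.DataFrame(
        {
            "age_years": np.round(ages, 1),
            "tobacco_smoking_history_indicator": rng.choice(
                _SMOKING_LEVELS, size=n, p=_SMOKING_PROBS
            ),
            "ajcc_pathologic_tumor_stage": rng.choice(_STAGE_LEVELS, size=n, p=_STAGE_PROBS),
            "transversion_status": rng.choice(
                list(_TRANSVERSION_PROBS), size=n, p=list(_TRANSVERSION_PROBS.values())
            ),
        },
        index=pd.Index(patients, name="patient_id"),
    )
    truth = {
        "signature_names": sig_names,
        "exposure_fractions": pd.DataFrame(
            fractions, index=clinical.index, columns=sig_names
        ),
        "n_mutations": pd.Series(n_mutations, index=clinical.index, name="n_mutations"),
        "age_rho_targets": dict(config.age_rho_targets),
    }
    return clinical, truth


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def _random_context(rng: np.random.Generator, center: str) -> str:
    """11-mer with the given center trinucleotide, guaranteed repeat-clean."""
    for _ in range(100):
        left = "".join(rng.choice(list(BASES), size=4))
        right = "".join(rng.choice(list(BASES), size=4))
        ctx = left + center + right
        if repeat_context_pass(ctx):
            return ctx
    raise RuntimeError("could not draw a repeat-clean context")  # pragma: no cover


def _failing_context(rng: np.random.Generator, ref: str) -> str:
    """11-mer with a >=6-base homopolymer of the ref base crossing the center.

    The run must include the center position (index 5) so that the context
    still satisfies center-base == ref; such records are exactly the ones the
    repeat filter removes, so their channel content is irrelevant downstream.
    """
    ctx = list(rng.choice(list(BASES), size=11))
    start = int(rng.integers(0, 6))  # run covers indices start..start+5 ∋ 5
    for i in range(start, start + 6):
        ctx[i] = ref
    return "".join(ctx)


def _render_snv(rng: np.random.Generator, channel: str, failing: bool) -> tuple[str, str, str]:
    """ref, alt, 11-mer context realizing a channel, strand randomized 50/50."""
    five, sub, three = channel[0], channel[2:5], channel[6]
    ref, alt = sub[0], sub[2]
    if rng.random() < 0.5:  # report on the purine strand
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    if failing:
        return ref, alt, _failing_context(rng, ref)
    return ref, alt, _random_context(rng, five + ref + three)


_NONSILENT = ("Missense_Mutation", "Nonsense_Mutation", "Splice_Site")
_NONSILENT_PROBS = (0.80, 0.15, 0.05)
_INDEL = (("Frame_Shift_Del", "DEL"), ("Frame_Shift_Ins", "INS"))


def simulate_maf(
    clinical: pd.DataFrame,
    truth: dict,
    catalog: SignatureCatalog,
    config: SimulationConfig,
) -> pd.DataFrame:
    """MAF-like table drawn from each patient's signature mixture.

    Channels are multinomial from Σ fᵢ·SIᵢ; each record is rendered with
    strand randomized 50/50 (exercising pyrimidine normalization) and a clean
    11-mer context. Configured fractions of duplicate-sample rows, two-gene
    annotations and repeat-failing contexts are injected. Positions are unique
    per patient, so the only duplicates are the injected ones.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sig_idx = [catalog.signature_labels.index(s) for s in truth["signature_names"]]
    genes = np.array(config.gene_universe)
    dup_odds = (
        config.duplicate_fraction / (1.0 - config.duplicate_fraction)
        if config.duplicate_fraction < 1.0
        else 1.0
    )
    rows = []
    for patient in clinical.index:
        n_mut = int(truth["n_mutations"].loc[patient])
        fracs = truth["exposure_fractions"].loc[patient].to_numpy()
        mixture = catalog.matrix[:, sig_idx] @ fracs
        mixture = mixture / mixture.sum()
        n_indel = rng.binomial(n_mut, config.indel_fraction)
        n_snv = n_mut - n_indel
        channel_counts = rng.multinomial(n_snv, mixture)
        sample = f"{patient}-01A"
        pos = 0
        for ch_i in np.repeat(np.arange(96), channel_counts):
            pos += int(rng.integers(1, 5000))
            failing = rng.random() < config.repeat_context_fraction
            ref, alt, ctx = _render_snv(rng, CHANNELS_96[ch_i], failing)
            if rng.random() < config.silent_fraction:
                classification = "Silent"
            else:
                classification = rng.choice(_NONSILENT, p=_NONSILENT_PROBS)
            gene = rng.choice(genes)
            if rng.random() < config.multigene_fraction:
                gene = f"{gene};{rng.choice(genes)}"
            row = {
                "Tumor_Sample_Barcode": sample,
                "Hugo_Symbol": gene,
                "Chromosome": str(rng.integers(1, 23)),
                "Start_position": pos,
                "Reference_Allele": ref,
                "Tumor_Seq_Allele2": alt,
                "ref_context": ctx,
                "Variant_Classification": classification,
                "Variant_Type": "SNP",
            }
            rows.append(row)
            if rng.random() < dup_odds:
                dup = dict(row)
                dup["Tumor_Sample_Barcode"] = f"{patient}-06A"
                rows.append(dup)
        for _ in range(n_indel):
            pos += int(rng.integers(1, 5000))
            classification, vtype = _INDEL[rng.integers(0, 2)]
            ctx = _random_context(rng, "".join(rng.choice(list(BASES), size=3)))
            rows.append(
                {
                    "Tumor_Sample_Barcode": sample,
                    "Hugo_Symbol": rng.choice(genes),
                    "Chromosome": str(rng.integers(1, 23)),
                    "Start_position": pos,
                    "Reference_Allele": "A" if vtype == "DEL" else "-",
                    "Tumor_Seq_Allele2": "-" if vtype == "DEL" else "A",
                    "ref_context": ctx,
                    "Variant_Classification": classification,
                    "Variant_Type": vtype,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CNV and methylation matrices
# ---------------------------------------------------------------------------

def simulate_matrices(
    clinical: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene×patient CNV (thresholded calls) and methylation (beta) matrices.

    CNV events are Bernoulli per gene with a per-patient rate, log-normally
    jittered and optionally age-coupled (``cnv_age_rho``); event values are
    drawn from {-2,-1,1,2} with low-level events four times as likely.
    Methylation betas are a logistic transform of Gaussian scores whose
    per-patient dispersion is age-coupled so that the absolute-z change rate
    attains ``methylation_age_rho`` against age in expectation.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(clinical)
    ages = clinical["age_years"].to_numpy(dtype=float)
    z_age = sps.norm.ppf((sps.rankdata(ages) - 0.5) / n)

    r_cnv = _latent_corr(config.cnv_age_rho)
    z_cnv = r_cnv * z_age + math.sqrt(max(0.0, 1 - r_cnv**2)) * rng.standard_normal(n)
    rates = np.clip(config.cnv_event_rate * np.exp(0.5 * z_cnv), 0.0, 1.0)
    cnv_genes = [f"CNVG{i:04d}" for i in range(1, config.n_cnv_genes + 1)]
    events = rng.random((config.n_cnv_genes, n)) < rates
    values = rng.choice([-2, -1, 1, 2], size=events.shape, p=(0.1, 0.4, 0.4, 0.1))
    cnv = pd.DataFrame(
        np.where(events, values, 0), index=cnv_genes, columns=clinical.index
    )

    r_me = _latent_corr(config.methylation_age_rho)
    z_me = r_me * z_age + math.sqrt(max(0.0, 1 - r_me**2)) * rng.standard_normal(n)
    dispersion = np.exp(0.4 * z_me)
    meth_genes = [f"METHG{i:04d}" for i in range(1, config.n_methylation_genes + 1)]
    mu = rng.normal(0.0, 1.0, size=(config.n_methylation_genes, 1))
    noise = rng.standard_normal((config.n_methylation_genes, n))
    beta = 1.0 / (1.0 + np.exp(-(mu + dispersion[None, :] * noise)))
    methylation = pd.DataFrame(beta, index=meth_genes, columns=clinical.index)
    return cnv, methylation


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def simulate_gene_sets(
    gene_universe: list[str],
    n_sets: int = 10,
    set_size_range: tuple[int, int] = (10, 30),
    seed: int = 0,
    spike_name: str = "SPIKE_SET",
) -> GeneSetCollection:
    """Random gene sets over the universe, the first one designated 'spike'.

    The spike set (named ``spike_name``) is the target of enrichment
    simulations: tests inflate its genes' values in one subgroup and check it
    ranks first.
    """
    lo, hi = set_size_range
    if hi > len(gene_universe):
        raise ValueError("set size exceeds gene universe")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        name = spike_name if i == 0 else f"SET{i:02d}"
        size = int(rng.integers(lo, hi + 1))
        sets[name] = sorted(rng.choice(gene_universe, size=size, replace=False))
    return GeneSetCollection(sets, provenance="synthetic")


# ---------------------------------------------------------------------------
# full dataset on disk
# ---------------------------------------------------------------------------

def simulate_dataset(
    config: SimulationConfig,
    out_dir,
    catalog: SignatureCatalog | None = None,
) -> dict[str, Path]:
    """Write a complete synthetic dataset (TSVs, GMT, ground-truth JSON)."""
    from .signatures import default_catalog

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = catalog or default_catalog()
    clinical, truth = simulate_cohort(config)
    maf = simulate_maf(clinical, truth, catalog, config)
    cnv, methylation = simulate_matrices(clinical, config)
    gene_sets = simulate_gene_sets(config.gene_universe, seed=config.seed)

    paths = {
        "maf": out / "mutations.maf",
        "clinical": out / "clinical.tsv",
        "cnv": out / "cnv_thresholded.tsv",
        "methylation": out / "methylation_beta.tsv",
        "gmt": out / "gene_sets.gmt",
        "truth": out / "ground_truth.json",
    }
    maf.to_csv(paths["maf"], sep="\t", index=False)
    clinical.to_csv(paths["clinical"], sep="\t")
    cnv.to_csv(paths["cnv"], sep="\t", index_label="gene")
    methylation.to_csv(paths["methylation"], sep="\t", index_label="gene")
    write_gmt(gene_sets, paths["gmt"])
    truth_json = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "exposure_fractions": truth["exposure_fractions"].round(6).to_dict(orient="index"),
        "n_mutations": truth["n_mutations"].to_dict(),
        "age_rho_targets": truth["age_rho_targets"],
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth_json, fh, indent=1)
    return paths
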