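"""Refitting of 96-channel mutation profiles to a fixed signature catalog.

A tumor's profile p (96 counts) is modelled as a non-negative linear
combination of the catalog columns S (96×K, column-stochastic):

    p ≈ a1·S1 + a2·S2 + … + aK·SK,   a ≥ 0

and the exposures a are estimated by bound-constrained quasi-Newton
minimization (L-BFGS-B with analytic gradient) of the residual sum of squares
||p − S a||². The objective is convex, so the optimum is
initialization-independent and coincides with the non-negative least-squares
solution; exposures come out in mutation-count units (Σaᵢ ≈ total mutations
when the fit is good).

The model is exposed statsmodels-style: ``SignatureRefit(profiles, catalog)``
is the model, ``.fit()`` returns a :class:`SignatureRefitResults` carrying the
exposure matrix, per-patient diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .profiles import CHANNELS_96

__all__ = [
    "SignatureCatalog",
    "load_signature_catalog",
    "default_catalog",
    "ExposureVector",
    "fit_exposures",
    "exposure_table",
    "SignatureRefit",
    "SignatureRefitResults",
]


@dataclass(frozen=True)
class SignatureCatalog:
    """Column-stochastic 96×K matrix of signature channel probabilities."""

    matrix: np.ndarray  # (96, K)
    channel_labels: tuple[str, ...]
    signature_labels: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (96, len(self.signature_labels)):
            raise ValueError(f"catalog shape {m.shape} does not match labels")
        if (m < 0).any():
            raise ValueError("catalog contains negative entries")
        sums = m.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = [self.signature_labels[i] for i in np.where(np.abs(sums - 1.0) > 1e-3)[0]]
            raise ValueError(f"non-column-stochastic signature column(s): {bad}")
        if tuple(self.channel_labels) != CHANNELS_96:
            raise ValueError("channel labels are not in canonical order")

    @property
    def n_signatures(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.channel_labels), columns=list(self.signature_labels)
        )


def load_signature_catalog(path) -> SignatureCatalog:
    """Load and validate a signature catalog TSV.

    Expected layout: a channel-label column (``SomaticMutationType`` or the
    first column) and one numeric column per signature. Rows may be in any
    order; they are re-indexed to the canonical channel order by label.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    label_col = "SomaticMutationType" if "SomaticMutationType" in df.columns else df.columns[0]
    df = df.set_index(label_col)
    unknown = set(df.index) - set(CHANNELS_96)
    if unknown:
        raise ValueError(f"unknown channel label(s): {sorted(unknown)[:5]}")
    if len(df) != 96 or df.index.duplicated().any():
        raise ValueError(f"catalog must have exactly the 96 channels, got {len(df)} rows")
    df = df.loc[list(CHANNELS_96)]
    return SignatureCatalog(
        matrix=df.to_numpy(dtype=float),
        channel_labels=CHANNELS_96,
        signature_labels=tuple(df.columns),
    )


def default_catalog() -> SignatureCatalog:
    """The shipped synthetic 96×30 catalog (see data/synthetic_signatures_96x30.tsv)."""
    ref = importlib.resources.files("luscage.data").joinpath("synthetic_signatures_96x30.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_signature_catalog(path)


@dataclass
class ExposureVector:
    """Fitted signature exposures for one patient, in mutation-count units."""

    patient_id: str
    a: np.ndarray  # (K,), all >= 0
    objective: float  # residual sum of squares at the optimum
    reconstruction_cosine: float
    n_mutations: int
    converged: bool = True


def _cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return float("nan")
    return float(u @ v / (nu * nv))


def fit_exposures(
    profile: np.ndarray,
    catalog: SignatureCatalog,
    patient_id: str = "",
    maxiter: int = 10_000,
    ftol: float = 1e-10,
    x0: np.ndarray | None = None,
) -> ExposureVector:
    """Minimize ||p − S a||² over a ≥ 0 with L-BFGS-B and analytic gradient.

    ``ftol`` is the relative objective-change stopping tolerance. The default
    start is the scale-aware uniform point aᵢ = n_mutations/K; convexity makes
    the optimum independent of it.
    """
    p = np.asarray(profile, dtype=float)
    if p.shape != (96,):
        raise ValueError(f"profile must have shape (96,), got {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError("profile contains non-finite counts")
    S = catalog.matrix
    K = catalog.n_signatures
    n_mut = int(round(p.sum()))
    if p.sum() == 0:
        return ExposureVector(patient_id, np.zeros(K), 0.0, float("nan"), 0)

    StS = S.T @ S
    Stp = S.T @ p
    ppt = float(p @ p)

    def objective(a: np.ndarray) -> tuple[float, np.ndarray]:
        # ||p - Sa||^2 = p'p - 2 a'S'p + a'S'S a ; grad = 2(S'S a - S'p)
        f = ppt - 2.0 * (a @ Stp) + a @ StS @ a
        g = 2.0 * (StS @ a - Stp)
        return f, g

    if x0 is None:
        x0 = np.full(K, p.sum() / K)
    res = optimize.minimize(
        objective,
        x0=x0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * K,
        options={"maxiter": maxiter, "ftol": ftol, "gtol": 1e-12},
    )
    if not res.success and res.status != 1:  # status 1 = maxiter reached
        raise RuntimeError(f"exposure fit failed for {patient_id!r}: {res.message}")
    a = np.maximum(res.x, 0.0)  # clamp -0.0 / roundoff at the active bound
    recon = S @ a
    rss = float(np.sum((p - recon) ** 2))
    return ExposureVector(
        patient_id=patient_id,
        a=a,
        objective=rss,
        reconstruction_cosine=_cosine(p, recon),
        n_mutations=n_mut,
        converged=bool(res.success),
    )


class SignatureRefit:
    """Model: per-patient signature exposures for a profile matrix.

    Parameters
    ----------
    profiles : pandas.DataFrame
        patients×96 count matrix, columns in canonical channel order
        (as produced by :func:`luscage.profiles.profile_matrix`).
    catalog : SignatureCatalog, optional
        Defaults to the shipped synthetic catalog.
    """

    def __init__(self, profiles: pd.DataFrame, catalog: SignatureCatalog | None = None):
        if list(profiles.columns) != list(CHANNELS_96):
            raise ValueError("profile matrix columns must be the 96 canonical channels")
        self.profiles = profiles
        self.catalog = catalog if catalog is not None else default_catalog()

    @classmethod
    def from_records(cls, records, catalog: SignatureCatalog | None = None) -> "SignatureRefit":
        from .profiles import build_patient_profiles, profile_matrix

        return cls(profile_matrix(build_patient_profiles(records)), catalog)

    def fit(self, maxiter: int = 10_000, ftol: float = 1e-10) -> "SignatureRefitResults":
        fits = [
            fit_exposures(row.to_numpy(float), self.catalog, patient_id=str(pid),
                          maxiter=maxiter, ftol=ftol)
            for pid, row in self.profiles.iterrows()
        ]
        return SignatureRefitResults(self, fits)


class SignatureRefitResults:
    """Results of a SignatureRefit fit: exposures and reconstruction diagnostics."""

    def __init__(self, model: SignatureRefit, fits: list[ExposureVector]):
        self.model = model
        self.fits = fits
        sig = list(model.catalog.signature_labels)
        idx = pd.Index([f.patient_id for f in fits], name="patient_id")
        self.exposures = pd.DataFrame(
            np.vstack([f.a for f in fits]) if fits else np.zeros((0, len(sig))),
            index=idx, columns=sig,
        )

    @property
    def exposure_fractions(self) -> pd.DataFrame:
        totals = self.exposures.sum(axis=1)
        return self.exposures.div(totals.where(totals > 0), axis=0)

    @property
    def diagnostics(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_mutations": [f.n_mutations for f in self.fits],
                "objective": [f.objective for f in self.fits],
                "reconstruction_cosine": [f.reconstruction_cosine for f in self.fits],
                "exposure_total": [float(f.a.sum()) for f in self.fits],
                "converged": [f.converged for f in self.fits],
            },
            index=self.exposures.index,
        )

    def summary(self) -> str:
        diag = self.diagnostics
        mean_expo = self.exposures.mean(axis=0).sort_values(ascending=False)
        lines = [
            "Signature refitting results",
            "===========================",
            f"patients:            {len(self.fits)}",
            f"signatures:          {self.model.catalog.n_signatures}",
            f"median mutations:    {diag['n_mutations'].median():.0f}" if len(diag) else "",
            f"median recon cosine: {diag['reconstruction_cosine'].median():.4f}" if len(diag) else "",
            "",
            "Mean exposure (mutation counts), top 10:",
        ]
        for name, val in mean_expo.head(10).items():
            lines.append(f"  {name:<8s} {val:10.1f}")
        return "\n".join(line for line in lines if line != "")

    def to_tsv(self, path) -> None:
        self.exposures.to_csv(path, sep="\t")


def exposure_table(
    profiles: pd.DataFrame,
    catalog: SignatureCatalog | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """patients×K exposure matrix (functional convenience over SignatureRefit)."""
    return SignatureRefit(profiles, catalog).fit(**fit_kwargs).exposures
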