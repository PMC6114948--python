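"""96-channel trinucleotide substitution profiles.

Every single-base substitution is described by the pyrimidine of the mutated
Watson–Crick pair together with its immediate 5' and 3' flanking bases:
6 substitution types (C>A, C>G, C>T, T>A, T>C, T>G) × 4 × 4 flanks = 96
channels. A purine-reference event is reported on the opposite strand, which
complements ref/alt and swaps + complements the flanks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .maf import MutationRecord

__all__ = [
    "SUBSTITUTIONS",
    "BASES",
    "CHANNELS_96",
    "UnassignableVariant",
    "channel_label",
    "channel_index",
    "normalize_to_pyrimidine",
    "Profile96",
    "build_patient_profiles",
    "profile_matrix",
]

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES: str = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def channel_label(substitution: str, five: str, three: str) -> str:
    return f"{five}[{substitution}]{three}"


#: canonical channel order: substitution major, then 5' base, then 3' base
CHANNELS_96: tuple[str, ...] = tuple(
    channel_label(sub, five, three) for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS_96)}


class UnassignableVariant(ValueError):
    """Raised when a substitution cannot be mapped to one of the 96 channels."""


def channel_index(substitution: str, five: str, three: str) -> int:
    try:
        return _CHANNEL_INDEX[channel_label(substitution, five, three)]
    except KeyError:
        raise UnassignableVariant(
            f"no channel for {five}[{substitution}]{three}"
        ) from None


def normalize_to_pyrimidine(ref: str, alt: str, five: str, three: str) -> int:
    """Map a substitution with flanks to its canonical channel index.

    Pyrimidine reference (C/T): channel is five[ref>alt]three as given.
    Purine reference (A/G): the event is read from the opposite strand —
    all three positions complemented and the flanks swapped.
    """
    ref, alt, five, three = ref.upper(), alt.upper(), five.upper(), three.upper()
    for b in (ref, alt, five, three):
        if b not in _COMPLEMENT:
            raise UnassignableVariant(f"non-ACGT base {b!r}")
    if ref == alt:
        raise ValueError(f"ref == alt ({ref})")
    if ref in "AG":
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        five, three = _COMPLEMENT[three], _COMPLEMENT[five]
    return channel_index(f"{ref}>{alt}", five, three)


@dataclass
class Profile96:
    """Per-patient counts over the 96 trinucleotide substitution channels."""

    patient_id: str
    counts: np.ndarray  # shape (96,), non-negative ints
    n_unassigned: int = 0

    @property
    def n_mutations(self) -> int:
        return int(self.counts.sum())


def _classify(record: MutationRecord) -> int:
    ctx = record.ref_context
    center = len(ctx) // 2
    if len(ctx) < 3 or len(ctx) % 2 == 0:
        raise UnassignableVariant(f"context too short or even-length: {ctx!r}")
    return normalize_to_pyrimidine(
        record.ref_allele, record.alt_allele, ctx[center - 1], ctx[center + 1]
    )


def build_patient_profiles(records: list[MutationRecord]) -> dict[str, Profile96]:
    """Aggregate filtered records into one Profile96 per patient.

    Only SNP-type records contribute counts; indels and unassignable SNPs
    (N in context/alleles, malformed context) are tallied in ``n_unassigned``
    for SNPs and ignored for non-SNPs, so sum(counts) + n_unassigned equals the
    number of SNP records of the patient. Patients with only non-SNP records
    still appear, with an all-zero profile.
    """
    profiles: dict[str, Profile96] = {}
    for r in records:
        prof = profiles.get(r.patient_id)
        if prof is None:
            prof = profiles[r.patient_id] = Profile96(r.patient_id, np.zeros(96, dtype=np.int64))
        if r.variant_type != "SNP":
            continue
        try:
            prof.counts[_classify(r)] += 1
        except UnassignableVariant:
            prof.n_unassigned += 1
    return profiles


def profile_matrix(profiles: dict[str, Profile96]) -> pd.DataFrame:
    """patients×96 count matrix with COSMIC-style channel column labels."""
    index = sorted(profiles)
    data = np.vstack([profiles[p].counts for p in index]) if index else np.zeros((0, 96), int)
    return pd.DataFrame(data, index=pd.Index(index, name="patient_id"), columns=list(CHANNELS_96))
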