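"""96-channel trinucleotide mutation spectra and signature refitting.

Channel order is the conventional one: six pyrimidine-centred substitution
classes (C>A, C>G, C>T, T>A, T>C, T>G), each expanded over the 16 flanking
dinucleotide contexts in alphabetical order, e.g. ``A[C>A]A`` .. ``T[T>G]T``.
Exposures are refit by non-negative least squares on the frequency-normalized
spectrum and renormalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import nnls

from .errors import IntegrityError, ValidationError
from .variant_io import VariantRecord

__all__ = [
    "SUBSTITUTIONS",
    "CHANNELS",
    "channel_index",
    "extract_context",
    "MutationSpectrum",
    "SignatureMatrix",
    "ExposureVector",
    "fit_exposures",
    "dominant_signature",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: The 96 channel labels, in canonical order.
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def channel_index(five: str, ref: str, alt: str, three: str) -> int:
    """Map a stranded trinucleotide substitution to its canonical channel.

    Purine-reference substitutions are reverse-complemented (alleles and
    flanks) so the central base is a pyrimidine.
    """
    if ref in "AG":
        five, ref, alt, three = _revcomp(three), _revcomp(ref), _revcomp(alt), _revcomp(five)
    label = f"{five}[{ref}>{alt}]{three}"
    try:
        return _CHANNEL_INDEX[label]
    except KeyError:
        raise ValidationError(f"not a valid substitution context: {label}") from None


def _fetch(genome, chrom: str, start0: int, end0: int) -> str:
    """Fetch [start0, end0) from a pyfaidx.Fasta or a plain mapping of strings."""
    seq = genome[chrom][start0:end0]
    return str(seq).upper()


def extract_context(v: VariantRecord, genome) -> int:
    """Return the 0..95 channel index of an SNV given a reference genome.

    Raises IntegrityError when the genome base at the locus differs from the
    record's ref allele, and ValidationError for non-SNVs.
    """
    if not v.is_snv:
        raise ValidationError(f"not an SNV: {v.key}")
    tri = _fetch(genome, v.chrom, v.pos - 2, v.pos + 1)
    if len(tri) != 3:
        raise IntegrityError(f"cannot fetch trinucleotide context at {v.chrom}:{v.pos}")
    if tri[1] != v.ref:
        raise IntegrityError(
            f"reference mismatch at {v.chrom}:{v.pos}: genome has {tri[1]}, "
            f"record has {v.ref}"
        )
    return channel_index(tri[0], v.ref, v.alt, tri[2])


@dataclass
class MutationSpectrum:
    """Counts over the 96 canonical channels."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValidationError(f"spectrum must have 96 channels, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValidationError("spectrum counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_variants(cls, variants: Iterable[VariantRecord], genome) -> "MutationSpectrum":
        counts = np.zeros(96, dtype=int)
        for v in variants:
            if v.is_snv:
                counts[extract_context(v, genome)] += 1
        return cls(counts)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("channel\tcount\n")
            for label, c in zip(CHANNELS, self.counts):
                fh.write(f"{label}\t{int(c)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationSpectrum":
        counts = np.zeros(96, dtype=int)
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("channel"):
                raise ValidationError(f"{path}: expected 'channel\\tcount' header")
            for line in fh:
                label, c = line.rstrip("\n").split("\t")
                counts[_CHANNEL_INDEX[label]] = int(c)
        return cls(counts)


@dataclass
class SignatureMatrix:
    """Named signatures as rows of 96 channel probabilities (each summing to 1)."""

    names: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape != (len(self.names), 96):
            raise ValidationError(
                f"probs must be (n_signatures, 96), got {self.probs.shape}"
            )
        if np.any(self.probs < 0):
            raise ValidationError("signature probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValidationError("each signature row must sum to 1 (±1e-6)")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureMatrix":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = set(CHANNELS) - set(df.columns)
        if missing:
            raise ValidationError(f"{path}: missing channel columns, e.g. {sorted(missing)[:3]}")
        return cls(names=list(df.index), probs=df[list(CHANNELS)].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("signature\t" + "\t".join(CHANNELS) + "\n")
            for name, row in zip(self.names, self.probs):
                fh.write(name + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


@dataclass
class ExposureVector:
    names: list[str]
    shares: np.ndarray
    residual_norm: float

    def __post_init__(self) -> None:
        self.shares = np.asarray(self.shares, dtype=float)
        if np.any(self.shares < 0):
            raise ValidationError("exposure shares must be non-negative")
        if abs(float(self.shares.sum()) - 1.0) > 1e-9:
            raise ValidationError("exposure shares must sum to 1")


def fit_exposures(spectrum: MutationSpectrum, sigs: SignatureMatrix) -> ExposureVector:
    """Non-negative least-squares refit of signature exposures to a spectrum."""
    if spectrum.total == 0:
        raise ValidationError("cannot fit an all-zero spectrum")
    b = spectrum.counts / spectrum.total
    x, residual = nnls(sigs.probs.T, b)
    total = x.sum()
    shares = x / total if total > 0 else np.full(len(x), 1.0 / len(x))
    return ExposureVector(names=list(sigs.names), shares=shares, residual_norm=float(residual))


def dominant_signature(e: ExposureVector, min_share: float = 0.4) -> str | None:
    """Name of the argmax signature when its share reaches ``min_share``, else None.

    Ties are broken by signature order (first wins).
    """
    i = int(np.argmax(e.shares))
    return e.names[i] if e.shares[i] >= min_share else None
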