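"""Mutation tables, trinucleotide channels and signature references.

Single-base substitutions are summarised in the 96-channel convention:
each SNV is collapsed onto the pyrimidine strand and keyed by its
substitution class (C>A, C>G, C>T, T>A, T>C, T>G) together with the
5' and 3' flanking bases.  A catalog is the per-channel count vector of
a mutation set; a signature reference is a channel-probability matrix
with one column per mutational signature (COSMIC layout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = ("C", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

STRAND_TRANSCRIBED = "transcribed"
STRAND_UNTRANSCRIBED = "untranscribed"
STRAND_INTERGENIC = "intergenic"
STRAND_UNKNOWN = "unknown"
STRAND_VALUES = (
    STRAND_TRANSCRIBED,
    STRAND_UNTRANSCRIBED,
    STRAND_INTERGENIC,
    STRAND_UNKNOWN,
)
#: strands that enter the 192-channel strand-split table
STRANDED = (STRAND_TRANSCRIBED, STRAND_UNTRANSCRIBED)


def _make_channels_96() -> tuple[str, ...]:
    channels = []
    for sub in SUBSTITUTIONS:
        ref = sub[0]
        for five in "ACGT":
            for three in "ACGT":
                channels.append(f"{five}[{sub}]{three}")
    return tuple(channels)


#: the 96 channels in canonical COSMIC order (substitution class major,
#: then 5' base, then 3' base, each alphabetical)
CHANNELS_96: tuple[str, ...] = _make_channels_96()
CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS_96)}

#: 192 strand-split channels: each 96-channel twice, transcribed first
CHANNELS_192: tuple[str, ...] = tuple(
    f"{strand[0].upper()}:{ch}" for ch in CHANNELS_96 for strand in STRANDED
)


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_context(ref: str, alt: str, five: str, three: str) -> str:
    """Map an SNV with flanking bases to its pyrimidine-centred 96-channel.

    Purine reference alleles are reverse-complemented (mutation and
    context together) so that the central base is C or T.

    Examples
    --------
    >>> collapse_context("C", "A", "A", "G")
    'A[C>A]G'
    >>> collapse_context("G", "T", "A", "C")   # revcomp of A_G_C is G_C_T
    'G[C>A]T'
    """
    for base in (ref, alt, five, three):
        if base not in COMPLEMENT:
            raise ValueError(f"non-ACGT base {base!r}")
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref!r})")
    if ref not in PYRIMIDINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five, three = COMPLEMENT[three], COMPLEMENT[five]
    return f"{five}[{ref}>{alt}]{three}"


@dataclass
class MutationRecord:
    """One somatic SNV with context, strand label and per-sample counts.

    ``per_sample`` maps sample name -> (alt_count, depth); ``ccf``
    optionally maps sample name -> cancer cell fraction in [0, 1].
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    context96: str
    strand: str = STRAND_UNKNOWN
    per_sample: dict[str, tuple[int, int]] = field(default_factory=dict)
    ccf: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref must differ from alt")
        if self.context96 not in CHANNEL_INDEX:
            raise ValueError(f"unknown channel {self.context96!r}")
        if self.strand not in STRAND_VALUES:
            raise ValueError(f"unknown strand {self.strand!r}")
        central = self.context96[2]
        expected = self.ref if self.ref in PYRIMIDINES else COMPLEMENT[self.ref]
        if central != expected:
            raise ValueError(
                f"context {self.context96} inconsistent with ref {self.ref}"
            )
        for sample, (alt_count, depth) in self.per_sample.items():
            if not 0 <= alt_count <= depth:
                raise ValueError(
                    f"sample {sample}: alt_count {alt_count} outside [0, {depth}]"
                )


@dataclass
class Catalog:
    """Ordered per-channel mutation counts (96 or 192 channels)."""

    channels: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.channels) != self.counts.shape[0]:
            raise ValueError("channels/counts length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative channel count")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        if self.n_total == 0:
            raise ValueError("empty catalog has no frequencies")
        return self.counts / self.n_total


def build_catalog(mutations: list[MutationRecord], strand_split: bool = False) -> Catalog:
    """Collapse mutations into a channel-count catalog.

    With ``strand_split`` the result is the 192-channel table restricted
    to transcribed/untranscribed mutations; intergenic and unknown
    records contribute only to the 96-channel marginal and are dropped
    here.
    """
    if not mutations:
        raise ValueError("empty mutation list")
    if not strand_split:
        counts = np.zeros(96, dtype=np.int64)
        for m in mutations:
            counts[CHANNEL_INDEX[m.context96]] += 1
        return Catalog(CHANNELS_96, counts)
    index = {c: i for i, c in enumerate(CHANNELS_192)}
    counts = np.zeros(192, dtype=np.int64)
    for m in mutations:
        if m.strand not in STRANDED:
            continue
        counts[index[f"{m.strand[0].upper()}:{m.context96}"]] += 1
    return Catalog(CHANNELS_192, counts)


@dataclass
class SignatureReference:
    """Channel-probability matrix, one column per signature.

    ``matrix`` has shape (96, n_signatures); each column sums to one.
    """

    names: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != (96, {len(self.names)})"
            )
        if np.any(self.matrix < 0):
            raise ValueError("negative signature probability")
        sums = self.matrix.sum(axis=0)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-3)
        if bad.size:
            raise ValueError(
                f"signature column(s) {[self.names[i] for i in bad]} do not sum to 1 "
                f"(sums {sums[bad]})"
            )
        # normalise away sub-tolerance drift so downstream maths is exact
        self.matrix = self.matrix / sums

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def subset(self, names: list[str]) -> "SignatureReference":
        missing = [n for n in names if n not in self.names]
        if missing:
            raise KeyError(f"unknown signature(s) {missing}")
        idx = [self.names.index(n) for n in names]
        return SignatureReference(tuple(names), self.matrix[:, idx])

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(CHANNELS_96), columns=list(self.names))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = ["chrom", "pos", "ref", "alt", "context96", "strand"]


def sample_names(mutations: list[MutationRecord]) -> list[str]:
    """Sorted union of sample names over a mutation list."""
    names: set[str] = set()
    for m in mutations:
        names.update(m.per_sample)
    return sorted(names)


def write_mutation_table(mutations: list[MutationRecord], path) -> None:
    samples = sample_names(mutations)
    rows = []
    for m in mutations:
        row = {
            "chrom": m.chrom,
            "pos": m.pos,
            "ref": m.ref,
            "alt": m.alt,
            "context96": m.context96,
            "strand": m.strand,
        }
        for s in samples:
            alt_count, depth = m.per_sample.get(s, (0, 0))
            row[f"alt_count/{s}"] = alt_count
            row[f"depth/{s}"] = depth
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_mutation_table(path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing column(s) {missing}")
    alt_cols = [c for c in df.columns if c.startswith("alt_count/")]
    samples = [c.split("/", 1)[1] for c in alt_cols]
    for s in samples:
        if f"depth/{s}" not in df.columns:
            raise ValueError(f"missing depth column for sample {s}")
    records = []
    for row in df.itertuples(index=False, name=None):
        values = dict(zip(df.columns, row))
        records.append(
            MutationRecord(
                chrom=str(values["chrom"]),
                pos=int(values["pos"]),
                ref=values["ref"],
                alt=values["alt"],
                context96=values["context96"],
                strand=values["strand"],
                per_sample={
                    s: (int(values[f"alt_count/{s}"]), int(values[f"depth/{s}"]))
                    for s in samples
                },
            )
        )
    return records


def write_signature_reference(reference: SignatureReference, path) -> None:
    df = reference.to_frame()
    df.index.name = "Type"
    df.to_csv(path, sep="\t")


def read_signature_reference(path) -> SignatureReference:
    """Read a COSMIC-format signature TSV (channel label column + one
    column per signature).  Rows are reordered into canonical channel
    order; column sums are validated to 1 within 1e-3."""
    df = pd.read_csv(path, sep="\t")
    label_col = df.columns[0]
    labels = df[label_col].astype(str)
    unknown = [l for l in labels if l not in CHANNEL_INDEX]
    if unknown:
        raise ValueError(f"unknown channel label(s) {unknown[:3]}")
    if len(labels) != 96 or len(set(labels)) != 96:
        raise ValueError("signature reference must have exactly the 96 channels")
    df = df.set_index(label_col).loc[list(CHANNELS_96)]
    return SignatureReference(tuple(df.columns), df.to_numpy(dtype=float))


def context_from_fasta(fasta_path, chrom: str, pos: int, ref: str, alt: str) -> str:
    """Look up the trinucleotide context from an indexed FASTA.

    Optional convenience for tables lacking a context column; positions
    are 1-based.  Requires pyfaidx.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    seq = str(fa[chrom][pos - 2 : pos + 1]).upper()
    if len(seq) != 3:
        raise ValueError(f"position {chrom}:{pos} too close to contig edge")
    if seq[1] != ref.upper():
        raise ValueError(
            f"reference base mismatch at {chrom}:{pos}: FASTA has {seq[1]}, table has {ref}"
        )
    return collapse_context(ref.upper(), alt.upper(), seq[0], seq[2])


def count_matrices(mutations: list[MutationRecord]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack per-sample (alt, depth) counts into (n, S) integer arrays."""
    samples = sample_names(mutations)
    n = len(mutations)
    alt = np.zeros((n, len(samples)), dtype=np.int64)
    depth = np.zeros((n, len(samples)), dtype=np.int64)
    for i, m in enumerate(mutations):
        for j, s in enumerate(samples):
            a, d = m.per_sample.get(s, (0, 0))
            alt[i, j], depth[i, j] = a, d
    return alt, depth, samples
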