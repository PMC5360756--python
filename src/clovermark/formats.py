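"""Readers and writers for every external representation the pipeline touches.

Downstream modules consume only the domain types defined here (plus
:class:`~clovermark.variants.VariantRecord` and
:class:`~clovermark.diversity.TreeNode`): FASTA coding sequences, a VCF 4.x
subset for SNPs, a TSV band-presence matrix for pooled gel scoring, a TSV
tetraploid genotype-count table, and Newick for dendrograms.

All user-facing coordinates are 1-based inclusive (VCF convention).
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import pysam
from Bio import SeqIO

from clovermark.report import atomic_write
from clovermark.variants import VariantRecord

if TYPE_CHECKING:  # pragma: no cover
    from clovermark.diversity import TreeNode

logger = logging.getLogger(__name__)

_FASTA_ALPHABET = frozenset("ACGTN")
_NEWICK_UNSAFE = re.compile(r"[\s()\[\]:;,']")


@dataclass(frozen=True)
class SequenceSet:
    """A set of named DNA sequences over {A,C,G,T,N}, uppercase, unique ids."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for seq_id, seq in self.records:
            if not seq_id:
                raise ValueError("empty sequence id")
            if seq_id in seen:
                raise ValueError(f"duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            if not seq:
                raise ValueError(f"empty sequence for id {seq_id!r}")
            bad = set(seq) - _FASTA_ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {seq_id!r} contains characters outside ACGTN: "
                    f"{sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.records)

    @property
    def total_bp(self) -> int:
        return sum(len(r[1]) for r in self.records)


def read_fasta(path: str | os.PathLike) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Sequences are uppercased; the record id is the first
    whitespace-delimited header token. Empty files, duplicate ids and
    characters outside {A,C,G,T,N} are rejected with the offending record
    named.
    """
    records: list[tuple[str, str]] = []
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _FASTA_ALPHABET
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records found in {os.fspath(path)!r}")
    return SequenceSet(tuple(records))


def write_fasta(seqs: SequenceSet, path: str | os.PathLike, width: int = 70) -> None:
    with atomic_write(path) as out:
        for seq_id, seq in seqs:
            out.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF


@dataclass
class VariantReadResult:
    """SNP records plus counts of rows set aside during parsing."""

    records: list[VariantRecord]
    n_indels_skipped: int = 0
    n_unfilterable: int = 0


def read_variants(path: str | os.PathLike) -> VariantReadResult:
    """Read SNP rows from a VCF 4.x file.

    Rows with a multi-base reference, or whose alternatives contain no
    single base, are skipped as indels and counted. Mixed SNP/indel
    alternative lists keep only the 1-bp alternatives. Depth is taken from
    FORMAT/DP of the first sample when present, else INFO/DP (the
    sample-level value is the per-site evidence the quality filter
    intends). Rows with missing QUAL or depth are kept but flagged
    unfilterable and counted.
    """
    result = VariantReadResult(records=[])
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for row in vcf.fetch():
            if row.alts is None or len(row.ref) != 1 or row.ref.upper() not in "ACGT":
                result.n_indels_skipped += 1
                continue
            alts = tuple(
                a.upper() for a in row.alts if len(a) == 1 and a.upper() in "ACGT"
            )
            if not alts:
                result.n_indels_skipped += 1
                continue
            depth: int | None = None
            if row.samples:
                sample = row.samples[0]
                if "DP" in sample and sample["DP"] is not None:
                    depth = int(sample["DP"])
            if depth is None and "DP" in row.info:
                depth = int(row.info["DP"])
            qual = None if row.qual is None else float(row.qual)
            rec = VariantRecord(
                seq_id=row.chrom, pos=row.pos, ref=row.ref, alts=alts,
                qual=qual, depth=depth,
            )
            if rec.unfilterable:
                result.n_unfilterable += 1
            result.records.append(rec)
    logger.info(
        "read %d SNP records (%d indel rows skipped, %d unfilterable)",
        len(result.records), result.n_indels_skipped, result.n_unfilterable,
    )
    return result


# ---------------------------------------------------------------------------
# Band-presence matrix


@dataclass
class BandMatrix:
    """Varieties x bands presence/absence for one or more SSR markers.

    ``presence[marker][band][variety]`` is 0 or 1. A variety's profile for
    a marker is the set of bands scored present; a pooled sample with at
    least one band counts as amplified (group G1) for that marker.
    """

    varieties: tuple[str, ...]
    markers: tuple[str, ...]
    presence: dict[str, dict[str, dict[str, int]]] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.varieties:
            raise ValueError("band matrix needs at least one variety")
        if not self.markers:
            raise ValueError("band matrix needs at least one marker")
        if len(set(self.varieties)) != len(self.varieties):
            raise ValueError("duplicate variety labels")
        for marker in self.markers:
            for band, cells in self.presence[marker].items():
                for variety in self.varieties:
                    value = cells[variety]
                    if value not in (0, 1):
                        raise ValueError(
                            f"non-binary cell {value!r} for marker {marker!r}, "
                            f"band {band!r}, variety {variety!r}"
                        )

    def bands(self, marker: str) -> tuple[str, ...]:
        if marker not in self.presence:
            raise KeyError(f"unknown marker {marker!r}")
        return tuple(self.presence[marker])

    def profile(self, marker: str, variety: str) -> frozenset[str]:
        """Set of bands present for *variety* at *marker*."""
        if marker not in self.presence:
            raise KeyError(f"unknown marker {marker!r}")
        return frozenset(
            band for band, cells in self.presence[marker].items() if cells[variety]
        )


def read_band_matrix(path: str | os.PathLike) -> BandMatrix:
    """Read a TSV band matrix: header ``marker band variety_1 ... variety_k``.

    Variety order is preserved from the header. Lines starting with ``#``
    are comments. Non-binary cells, ragged rows and duplicate
    (marker, band) pairs are rejected with the offending location named.
    """
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty band matrix file {os.fspath(path)!r}")
    header = lines[0].split("\t")
    if len(header) < 3 or header[0] != "marker" or header[1] != "band":
        raise ValueError(
            "band matrix header must be 'marker<TAB>band<TAB>variety_1...', "
            f"got {header[:3]!r}"
        )
    varieties = tuple(header[2:])
    if len(set(varieties)) != len(varieties):
        raise ValueError("duplicate variety columns in band matrix header")

    markers: list[str] = []
    presence: dict[str, dict[str, dict[str, int]]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != 2 + len(varieties):
            raise ValueError(
                f"line {lineno}: expected {2 + len(varieties)} columns, got {len(cells)}"
            )
        marker, band = cells[0], cells[1]
        if marker not in presence:
            presence[marker] = {}
            markers.append(marker)
        if band in presence[marker]:
            raise ValueError(f"line {lineno}: duplicate (marker, band) pair ({marker!r}, {band!r})")
        row: dict[str, int] = {}
        for variety, cell in zip(varieties, cells[2:]):
            if cell not in ("0", "1"):
                raise ValueError(
                    f"line {lineno}: non-binary cell {cell!r} in column {variety!r}"
                )
            row[variety] = int(cell)
        presence[marker][band] = row
    return BandMatrix(varieties=varieties, markers=tuple(markers), presence=presence)


def write_band_matrix(
    bands: BandMatrix, path: str | os.PathLike, header_comment: str | None = None
) -> None:
    with atomic_write(path) as out:
        if header_comment:
            out.write(header_comment + "\n")
        out.write("marker\tband\t" + "\t".join(bands.varieties) + "\n")
        for marker in bands.markers:
            for band, cells in bands.presence[marker].items():
                values = "\t".join(str(cells[v]) for v in bands.varieties)
                out.write(f"{marker}\t{band}\t{values}\n")


# ---------------------------------------------------------------------------
# Tetraploid genotype counts

#: Dosage classes for a biallelic SNP in a tetraploid, by count of the
#: alternative allele A (reference allele R).
DOSAGE_CLASSES = ("RRRR", "RRRA", "RRAA", "RAAA", "AAAA")


@dataclass(frozen=True)
class GenotypeCountTable:
    """Per-locus counts of the five tetraploid dosage classes RRRR..AAAA."""

    loci: tuple[tuple[str, tuple[int, int, int, int, int]], ...]

    def __post_init__(self) -> None:
        for locus_id, counts in self.loci:
            if len(counts) != 5:
                raise ValueError(f"locus {locus_id!r}: expected 5 dosage-class counts")
            if any(c < 0 for c in counts):
                raise ValueError(f"locus {locus_id!r}: negative count")
            if sum(counts) < 1:
                raise ValueError(f"locus {locus_id!r}: total count must be >= 1")


def read_genotype_counts(path: str | os.PathLike) -> GenotypeCountTable:
    """Read a TSV of ``locus n_RRRR n_RRRA n_RRAA n_RAAA n_AAAA``."""
    loci: list[tuple[str, tuple[int, int, int, int, int]]] = []
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty genotype table {os.fspath(path)!r}")
    header = lines[0].split("\t")
    expected = ["locus", *(f"n_{c}" for c in DOSAGE_CLASSES)]
    if header != expected:
        raise ValueError(f"genotype table header must be {expected!r}, got {header!r}")
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != 6:
            raise ValueError(f"line {lineno}: expected 6 columns, got {len(cells)}")
        try:
            counts = tuple(int(c) for c in cells[1:])
        except ValueError as err:
            raise ValueError(f"line {lineno}: non-integer count") from err
        loci.append((cells[0], counts))  # type: ignore[arg-type]
    return GenotypeCountTable(tuple(loci))


def write_genotype_counts(
    table: GenotypeCountTable, path: str | os.PathLike, header_comment: str | None = None
) -> None:
    with atomic_write(path) as out:
        if header_comment:
            out.write(header_comment + "\n")
        out.write("locus\t" + "\t".join(f"n_{c}" for c in DOSAGE_CLASSES) + "\n")
        for locus_id, counts in table.loci:
            out.write(locus_id + "\t" + "\t".join(str(c) for c in counts) + "\n")


# ---------------------------------------------------------------------------
# Newick


def _quote_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def newick_string(tree: "TreeNode") -> str:
    """Serialize a rooted binary tree with heights into Newick.

    Branch lengths are parent height minus child height; labels containing
    Newick metacharacters are single-quoted.
    """

    def _node(node: "TreeNode", parent_height: float | None) -> str:
        if node.children:
            inner = ",".join(_node(c, node.height) for c in node.children)
            text = f"({inner})"
        else:
            if not node.label:
                raise ValueError("unlabeled leaf in tree")
            text = _quote_label(node.label)
        if parent_height is not None:
            branch = float(parent_height) - float(node.height)
            text += f":{branch!r}"
        return text

    return _node(tree, None) + ";"


def write_newick(tree: "TreeNode", path: str | os.PathLike) -> None:
    with atomic_write(path) as out:
        out.write(newick_string(tree) + "\n")
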