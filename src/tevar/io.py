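"""Readers and writers for the external formats shared by every stage.

Internally all coordinates are 0-based half-open (BED convention); 1-based
coordinates appear only at the SAM/GFF boundary.  Genotype matrices are
pandas DataFrames (variants x accessions) holding float 1.0 / 0.0 / NaN,
serialised as TSV with cells ``1``, ``0`` or ``NA``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file did not conform to its expected format."""


@dataclass(frozen=True, order=True)
class TEAnnotation:
    """One reference transposable element.

    Coordinates are 0-based half-open.  ``te_id`` is unique within an
    annotation set; ``family``/``superfamily`` name the TE taxonomy.
    """

    chrom: str
    start: int
    end: int
    te_id: str
    family: str = "."
    superfamily: str = "."
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"TE {self.te_id}: start ({self.start}) must be < end ({self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths, centromere midpoints and masked chromosomes."""

    chrom_lengths: dict[str, int]
    centromeres: dict[str, int] = field(default_factory=dict)
    masked: tuple[str, ...] = ()
    pericentromere_bp: int = 3_000_000

    def __post_init__(self) -> None:
        for chrom, pos in self.centromeres.items():
            if chrom in self.chrom_lengths and not 0 <= pos <= self.chrom_lengths[chrom]:
                raise ValueError(f"centromere of {chrom} outside chromosome bounds")

    @property
    def chroms(self) -> list[str]:
        return [c for c in self.chrom_lengths if c not in self.masked]

    @property
    def unmasked_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chroms)

    def is_pericentromeric(self, chrom: str, pos: int) -> bool:
        """True within ``pericentromere_bp`` of the centromere midpoint."""
        mid = self.centromeres.get(chrom)
        if mid is None:
            return False
        return abs(pos - mid) < self.pericentromere_bp


@dataclass(frozen=True)
class VariantRecord:
    """A serialisable TE variant call for one accession.

    ``variant_type`` is ``presence`` (TE present in the accession, missing
    from the reference) or ``absence`` (reference TE missing from the
    accession).  Coordinates give the breakpoint interval (presence) or the
    spanned TE interval (absence).
    """

    variant_id: str
    chrom: str
    start: int
    end: int
    variant_type: str
    te_ids: tuple[str, ...]
    accession: str = "."
    n_split: int = 0
    n_discordant: int = 0
    evidence_read_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.variant_type not in ("presence", "absence"):
            raise ValueError(f"bad variant_type {self.variant_type!r}")
        if self.n_split < 0 or self.n_discordant < 0:
            raise ValueError("support counts must be >= 0")


# ---------------------------------------------------------------------------
# TE annotation (BED / GFF)
# ---------------------------------------------------------------------------

_GFF_ATTR = re.compile(r"(\w+)\s*=\s*([^;]+)")


def _looks_like_gff(path: Path) -> bool:
    if path.suffix.lower() in (".gff", ".gff3", ".gtf"):
        return True
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            return len(cols) == 9 and "=" in cols[8]
    return False


def read_te_annotation(
    path: str | Path, mask: Sequence[str] = ()
) -> list[TEAnnotation]:
    """Read a TE annotation from BED6+2 or GFF.

    BED columns: chrom, start, end, te_id, score, strand[, family,
    superfamily].  GFF records are 1-based inclusive and converted to
    0-based half-open; ``ID``/``Name`` give te_id and ``family``/
    ``superfamily`` attributes are honoured when present (falling back to
    the type and source columns).  Records on ``mask`` chromosomes are
    dropped.  Returns records sorted by (chrom, start).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    gff = _looks_like_gff(path)
    out: list[TEAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                cols = line.split()
            try:
                if gff:
                    if len(cols) != 9:
                        raise FormatError("expected 9 GFF columns")
                    chrom = cols[0]
                    start, end = int(cols[3]) - 1, int(cols[4])
                    attrs = dict(_GFF_ATTR.findall(cols[8]))
                    te_id = attrs.get("ID") or attrs.get("Name")
                    if te_id is None:
                        raise FormatError("GFF record lacks ID/Name attribute")
                    family = attrs.get("family", attrs.get("Family", cols[2]))
                    superfamily = attrs.get(
                        "superfamily", attrs.get("Superfamily", cols[1])
                    )
                    strand = cols[6] if cols[6] in "+-" else "+"
                else:
                    if len(cols) < 4:
                        raise FormatError("expected >=4 BED columns")
                    chrom = cols[0]
                    start, end = int(cols[1]), int(cols[2])
                    te_id = cols[3]
                    strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "+"
                    family = cols[6] if len(cols) > 6 else "."
                    superfamily = cols[7] if len(cols) > 7 else "."
                if end <= start:
                    raise FormatError(f"end ({end}) <= start ({start})")
                ann = TEAnnotation(chrom, start, end, te_id, family, superfamily, strand)
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}, line {lineno}: {exc}") from exc
            if chrom in mask:
                continue
            if te_id in seen:
                raise FormatError(f"{path}, line {lineno}: duplicate te_id {te_id!r}")
            seen.add(te_id)
            out.append(ann)
    out.sort()
    return out


def write_te_annotation(annotation: Iterable[TEAnnotation], path: str | Path) -> None:
    """Write TE records as BED6+2 (family, superfamily in columns 7-8)."""
    with open(path, "w") as fh:
        for te in sorted(annotation):
            fh.write(
                f"{te.chrom}\t{te.start}\t{te.end}\t{te.te_id}\t.\t{te.strand}"
                f"\t{te.family}\t{te.superfamily}\n"
            )


# ---------------------------------------------------------------------------
# Alignments (SAM/BAM via pysam)
# ---------------------------------------------------------------------------


def open_alignments(path: str | Path) -> pysam.AlignmentFile:
    """Open a coordinate-sorted SAM/BAM file.

    Raises :class:`FormatError` with instructions if the header does not
    declare coordinate sorting.
    """
    path = Path(path)
    afile = pysam.AlignmentFile(str(path), require_index=False, check_sq=True)
    so = afile.header.to_dict().get("HD", {}).get("SO", "unknown")
    if so != "coordinate":
        raise FormatError(
            f"{path} is not coordinate-sorted (SO={so}); run "
            "'samtools sort' and 'samtools index' first"
        )
    return afile


def read_alignments(
    path: str | Path, mask: Sequence[str] = ()
) -> Iterator[pysam.AlignedSegment]:
    """Stream alignment records, skipping masked chromosomes."""
    with open_alignments(path) as afile:
        for rec in afile:
            if rec.is_unmapped or rec.reference_name in mask:
                continue
            yield rec


# ---------------------------------------------------------------------------
# Variant call TSV
# ---------------------------------------------------------------------------

_CALL_COLUMNS = [
    "chrom",
    "start",
    "end",
    "variant_id",
    "variant_type",
    "te_ids",
    "accession",
    "n_split",
    "n_discordant",
    "evidence_read_names",
]


def write_variant_calls(calls: Iterable[VariantRecord], path: str | Path) -> None:
    """Write calls as a BED-like TSV (one dialect for presence and absence)."""
    rows = [
        (
            c.chrom,
            c.start,
            c.end,
            c.variant_id,
            c.variant_type,
            ",".join(c.te_ids),
            c.accession,
            c.n_split,
            c.n_discordant,
            ",".join(c.evidence_read_names),
        )
        for c in calls
    ]
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_calls(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            VariantRecord(
                variant_id=row.variant_id,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                variant_type=row.variant_type,
                te_ids=tuple(t for t in row.te_ids.split(",") if t),
                accession=row.accession,
                n_split=int(row.n_split),
                n_discordant=int(row.n_discordant),
                evidence_read_names=tuple(
                    n for n in row.evidence_read_names.split(",") if n
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Genotype matrix TSV
# ---------------------------------------------------------------------------


def write_genotype_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a variants x accessions matrix with cells 1 / 0 / NA."""
    bad = set(np.unique(matrix.to_numpy(dtype=float))) - {0.0, 1.0} - {
        v for v in [np.nan] if True
    }
    bad = {v for v in bad if not np.isnan(v)}
    if bad:
        raise FormatError(f"genotype matrix holds values other than 0/1/NA: {bad}")
    out = matrix.astype("Int8")
    out.index.name = "variant_id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_genotype_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    mapping = {"1": 1.0, "0": 0.0, "NA": np.nan, "": np.nan}
    arr = np.empty(df.shape, dtype=float)
    values = df.to_numpy()
    for (i, j), tok in np.ndenumerate(values):
        try:
            arr[i, j] = mapping[tok]
        except KeyError:
            raise FormatError(
                f"{path}: unknown genotype token {tok!r} at "
                f"variant {df.index[i]!r}, accession {df.columns[j]!r}"
            ) from None
    return pd.DataFrame(arr, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# Genome FASTA
# ---------------------------------------------------------------------------

_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP[a] = b


def revcomp(seq: np.ndarray) -> np.ndarray:
    """Reverse-complement an ASCII uint8 sequence array."""
    return _COMP[seq[::-1]]


def read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    """Read a genome FASTA into {chrom: ASCII uint8 array}."""
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = np.frombuffer(str(rec.seq).upper().encode(), dtype=np.uint8).copy()
    return genome


def write_fasta(genome: dict[str, np.ndarray], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(arr.tobytes().decode()), id=chrom, description="")
        for chrom, arr in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def layout_from_genome(
    genome: dict[str, np.ndarray],
    centromeres: dict[str, int] | None = None,
    masked: Sequence[str] = (),
) -> GenomeLayout:
    lengths = {c: int(len(s)) for c, s in genome.items()}
    if centromeres is None:
        centromeres = {c: n // 2 for c, n in lengths.items()}
    return GenomeLayout(lengths, centromeres, tuple(masked))
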