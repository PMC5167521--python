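"""Synthetic genomes, TE variants, reads and idealized alignments.

The generator produces a random low-repetition genome carrying annotated
TE copies, derives a second genome from it by planting copy-paste and
cut-paste transpositions and TE deletions, simulates paired-end reads
from the derived genome, and writes the alignments those reads would
have on the *reference* genome if mapping were perfect ("ideal
alignments").  Because every read's true origin is known, reads crossing
a planted breakpoint become split alignments and pairs straddling an
event become discordant pairs by construction, which makes the whole
caller testable without any external aligner.

Also provides population-scale matrix generators (genotypes, SNP/LD
panels, phenotypes with plantable rare-variant burden, methylation
matrices with plantable TE associations) used by the downstream
statistics modules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GenomeLayout, TEAnnotation, VariantRecord, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilySpec:
    name: str
    superfamily: str
    length: int


DEFAULT_FAMILIES = (
    FamilySpec("SIMCOPIA1", "LTR/Copia", 2_500),
    FamilySpec("SIMGYPSY1", "LTR/Gypsy", 4_500),
    FamilySpec("SIMGYPSY2", "LTR/Gypsy", 3_000),
    FamilySpec("SIMLINE1", "LINE/L1", 1_800),
    FamilySpec("SIMMUDR1", "DNA/MuDR", 1_200),
    FamilySpec("SIMHAT1", "DNA/HAT", 600),
    FamilySpec("SIMHELI1", "RC/Helitron", 900),
    FamilySpec("SIMSINE1", "SINE/tRNA", 300),
)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = _BASES[(_BASE_INDEX[out[hit]] + shift) % 4]
    return out


def simulate_genome(
    n_chrom: int = 2,
    chrom_length: int = 1_000_000,
    n_tes: int = 50,
    families: Sequence[FamilySpec] = DEFAULT_FAMILIES,
    seed: int = 0,
    mutation_rate: float = 0.02,
    min_gap: int = 1_000,
    end_margin: int = 3_000,
) -> tuple[dict[str, np.ndarray], list[TEAnnotation]]:
    """Generate a random genome with ``n_tes`` annotated TE copies.

    Each TE body is the family consensus with per-copy substitutions at
    ``mutation_rate`` so copies are distinct, mappable sequences.  TEs
    are carved into the background without overlap, at least ``min_gap``
    apart and ``end_margin`` from chromosome ends.  Identical seeds give
    identical genomes.
    """
    rng = np.random.default_rng(seed)
    mean_len = float(np.mean([f.length for f in families]))
    if n_tes * mean_len >= n_chrom * chrom_length / 2:
        raise SimulationError("requested TE content exceeds half the genome")
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    genome = {c: _random_sequence(rng, chrom_length) for c in chroms}
    consensus = {f.name: _random_sequence(rng, f.length) for f in families}

    annotation: list[TEAnnotation] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    tries = 0
    for i in range(n_tes):
        fam = families[i % len(families)]
        length = fam.length
        while True:
            tries += 1
            if tries > 200 * max(n_tes, 1):
                raise SimulationError("could not place TEs without overlap")
            chrom = chroms[rng.integers(0, n_chrom)]
            lo, hi = end_margin, chrom_length - end_margin - length
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            if all(
                start >= e + min_gap or start + length <= s - min_gap
                for s, e in occupied[chrom]
            ):
                break
        occupied[chrom].append((start, start + length))
        body = _mutate(rng, consensus[fam.name], mutation_rate)
        genome[chrom][start : start + length] = body
        strand = "+" if rng.random() < 0.5 else "-"
        annotation.append(
            TEAnnotation(
                chrom, start, start + length, f"TE{i + 1:05d}",
                fam.name, fam.superfamily, strand,
            )
        )
    annotation.sort()
    return genome, annotation


# ---------------------------------------------------------------------------
# Planting variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedInsertion:
    """A TE copy inserted into the derived genome at ``position``."""

    te_id: str
    family: str
    superfamily: str
    mechanism: str          # copy_paste | cut_paste
    chrom: str              # reference chromosome of the target site
    position: int           # reference breakpoint (0-based, between bases)
    source_chrom: str
    source_start: int
    source_end: int

    @property
    def length(self) -> int:
        return self.source_end - self.source_start


@dataclass(frozen=True)
class PlantedDeletion:
    """A reference TE excised from the derived genome."""

    te_id: str
    family: str
    chrom: str
    start: int
    end: int
    mechanism: str = "deletion"   # deletion | cut_paste_source


@dataclass(frozen=True)
class Block:
    """One contiguous slice of a derived chromosome lifted to the reference."""

    dstart: int
    dend: int
    ref_chrom: str
    ref_start: int


@dataclass
class SimulationTruth:
    """Everything known about the planted events, plus the liftover map."""

    insertions: list[PlantedInsertion]
    deletions: list[PlantedDeletion]
    cut_paste_sources: list[PlantedDeletion]
    blocks: dict[str, list[Block]]
    seed: int

    @property
    def excised(self) -> list[PlantedDeletion]:
        """All intervals absent from the derived genome (deletions plus
        cut-paste donor sites)."""
        return self.deletions + self.cut_paste_sources

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for ins in self.insertions:
            rows.append(
                ("insertion", ins.chrom, ins.position, ins.position, ins.te_id,
                 ins.family, ins.mechanism, ins.source_chrom, ins.source_start,
                 ins.source_end)
            )
        for dele in self.excised:
            rows.append(
                ("absence", dele.chrom, dele.start, dele.end, dele.te_id,
                 dele.family, dele.mechanism, ".", -1, -1)
            )
        pd.DataFrame(
            rows,
            columns=["event", "chrom", "start", "end", "te_id", "family",
                     "mechanism", "source_chrom", "source_start", "source_end"],
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, seed: int = 0) -> "SimulationTruth":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "source_chrom": str})
        ins, dels, cuts = [], [], []
        for row in df.itertuples(index=False):
            if row.event == "insertion":
                ins.append(
                    PlantedInsertion(
                        row.te_id, row.family, ".", row.mechanism, row.chrom,
                        int(row.start), row.source_chrom,
                        int(row.source_start), int(row.source_end),
                    )
                )
            else:
                rec = PlantedDeletion(
                    row.te_id, row.family, row.chrom, int(row.start),
                    int(row.end), row.mechanism,
                )
                (cuts if row.mechanism == "cut_paste_source" else dels).append(rec)
        return cls(ins, dels, cuts, {}, seed)


def identity_blocks(genome: dict[str, np.ndarray]) -> dict[str, list[Block]]:
    return {c: [Block(0, len(s), c, 0)] for c, s in genome.items()}


def apply_variants(
    genome: dict[str, np.ndarray],
    annotation: Sequence[TEAnnotation],
    n_copy_paste: int = 50,
    n_cut_paste: int = 50,
    n_deletions: int = 100,
    seed: int = 0,
    min_event_gap: int = 6_000,
    min_source_target_dist: int = 25_000,
    target_te_margin: int = 2_000,
    end_margin: int = 3_000,
) -> tuple[dict[str, np.ndarray], SimulationTruth]:
    """Derive a genome by planting transpositions and deletions.

    Copy-paste leaves the donor TE intact; cut-paste excises it (the
    donor site becomes an additional absence in the derived genome, kept
    in ``truth.cut_paste_sources``).  Insertion targets land in TE-free
    background, at least ``min_event_gap`` from any other event and
    ``min_source_target_dist`` from their own donor so the split-read
    geometry matches a genuine dispersed transposition.  The derived
    length is exactly original + inserted - excised.
    """
    rng = np.random.default_rng(seed)
    anns = list(annotation)
    n_needed = n_copy_paste + n_cut_paste + n_deletions
    if n_needed > len(anns):
        raise SimulationError(
            f"need {n_needed} distinct TEs but annotation has {len(anns)}"
        )
    order = rng.permutation(len(anns))
    cut_tes = [anns[i] for i in order[:n_cut_paste]]
    del_tes = [anns[i] for i in order[n_cut_paste : n_cut_paste + n_deletions]]
    copy_tes = [anns[i] for i in order[n_cut_paste + n_deletions : n_needed]]

    chroms = list(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    # event intervals used for spacing checks (reference coordinates)
    spacing: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for te in cut_tes + del_tes:
        spacing[te.chrom].append((te.start, te.end))
    te_intervals: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for te in anns:
        te_intervals[te.chrom].append((te.start, te.end))

    def _clear(intervals: list[tuple[int, int]], pos: int, margin: int) -> bool:
        return all(pos <= s - margin or pos >= e + margin for s, e in intervals)

    insertions: list[PlantedInsertion] = []
    tries = 0
    for te, mech in [(t, "copy_paste") for t in copy_tes] + [
        (t, "cut_paste") for t in cut_tes
    ]:
        while True:
            tries += 1
            if tries > 500 * max(n_needed, 1):
                raise SimulationError("could not place insertion targets")
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(end_margin, lengths[chrom] - end_margin))
            if not _clear(te_intervals[chrom], pos, target_te_margin):
                continue
            if not _clear(spacing[chrom], pos, min_event_gap):
                continue
            if chrom == te.chrom and te.start - min_source_target_dist < pos < te.end + min_source_target_dist:
                continue
            break
        spacing[chrom].append((pos, pos))
        insertions.append(
            PlantedInsertion(
                te.te_id, te.family, te.superfamily, mech, chrom, pos,
                te.chrom, te.start, te.end,
            )
        )

    deletions = [
        PlantedDeletion(t.te_id, t.family, t.chrom, t.start, t.end, "deletion")
        for t in del_tes
    ]
    cut_sources = [
        PlantedDeletion(t.te_id, t.family, t.chrom, t.start, t.end, "cut_paste_source")
        for t in cut_tes
    ]

    derived: dict[str, np.ndarray] = {}
    blocks: dict[str, list[Block]] = {}
    for chrom in chroms:
        events: list[tuple[int, int, str, object]] = []
        for d in deletions + cut_sources:
            if d.chrom == chrom:
                events.append((d.start, d.end, "del", d))
        for ins in insertions:
            if ins.chrom == chrom:
                events.append((ins.position, ins.position, "ins", ins))
        events.sort(key=lambda t: (t[0], t[1]))
        parts: list[np.ndarray] = []
        chrom_blocks: list[Block] = []
        cur = 0
        dpos = 0

        def _add_ref(upto: int) -> None:
            nonlocal cur, dpos
            if upto > cur:
                parts.append(genome[chrom][cur:upto])
                chrom_blocks.append(Block(dpos, dpos + (upto - cur), chrom, cur))
                dpos += upto - cur
                cur = upto

        for start, end, kind, payload in events:
            _add_ref(start)
            if kind == "del":
                cur = end
            else:
                ins = payload
                body = genome[ins.source_chrom][ins.source_start : ins.source_end]
                parts.append(body)
                chrom_blocks.append(
                    Block(dpos, dpos + len(body), ins.source_chrom, ins.source_start)
                )
                dpos += len(body)
        _add_ref(lengths[chrom])
        derived[chrom] = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        blocks[chrom] = chrom_blocks

    expected = sum(lengths.values()) + sum(i.length for i in insertions) - sum(
        d.end - d.start for d in deletions + cut_sources
    )
    assert sum(len(s) for s in derived.values()) == expected, "length accounting"
    return derived, SimulationTruth(insertions, deletions, cut_sources, blocks, seed)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


@dataclass
class ReadProfile:
    """Sequencing library model: fold coverage, read length, insert-size
    normal distribution and per-base substitution error rate."""

    coverage: float
    read_length: int = 100
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    base_error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.coverage, self.read_length, self.insert_mean) <= 0:
            raise ValueError("coverage, read_length and insert_mean must be > 0")
        if self.insert_sd < 0 or not 0 <= self.base_error_rate < 1:
            raise ValueError("bad insert_sd or base_error_rate")


@dataclass
class ReadSet:
    """Paired reads with their true origins in the source genome.

    Sequences are stored in *genome* orientation; the right mate is
    reverse-complemented only when written as FASTQ.  Mate origins:
    left mate covers [frag_start, frag_start+read_length) on ``+``,
    right mate covers [frag_start+insert-read_length, frag_start+insert)
    on ``-``.
    """

    profile: ReadProfile
    chrom_names: list[str]
    chrom_idx: np.ndarray      # (n,) int32
    frag_start: np.ndarray     # (n,) int64
    insert: np.ndarray         # (n,) int32
    r1_is_left: np.ndarray     # (n,) bool
    seq_left: np.ndarray       # (n, read_length) uint8
    seq_right: np.ndarray      # (n, read_length) uint8

    @property
    def n_pairs(self) -> int:
        return len(self.frag_start)

    def name(self, i: int) -> str:
        return (
            f"sim{i:08d}:{self.chrom_names[self.chrom_idx[i]]}"
            f":{self.frag_start[i]}:{self.insert[i]}"
        )

    def to_fastq(self, path1: str | Path, path2: str | Path) -> None:
        rl = self.profile.read_length
        qual = "I" * rl
        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i in range(self.n_pairs):
                left = self.seq_left[i].tobytes().decode()
                right = revcomp(self.seq_right[i]).tobytes().decode()
                r1, r2 = (left, right) if self.r1_is_left[i] else (right, left)
                name = self.name(i)
                f1.write(f"@{name}/1\n{r1}\n+\n{qual}\n")
                f2.write(f"@{name}/2\n{r2}\n+\n{qual}\n")


def generate_reads(genome: dict[str, np.ndarray], profile: ReadProfile) -> ReadSet:
    """Simulate paired-end reads: pairs = round(cov * G / (2 * read_len)),
    insert sizes ~ Normal(mean, sd), i.i.d. substitution errors."""
    rng = np.random.default_rng(profile.seed)
    chroms = list(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    total = lengths.sum()
    rl = profile.read_length
    n_total = int(round(profile.coverage * total / (2 * rl)))
    quota = np.floor(n_total * lengths / total).astype(int)
    frac = n_total * lengths / total - quota
    for i in np.argsort(-frac)[: n_total - quota.sum()]:
        quota[i] += 1

    all_ci, all_fs, all_ins = [], [], []
    for ci, chrom in enumerate(chroms):
        n = quota[ci]
        if n == 0:
            continue
        L = len(genome[chrom])
        ins = np.rint(rng.normal(profile.insert_mean, profile.insert_sd, n))
        ins = np.clip(ins, rl, L - 1).astype(np.int64)
        fs = np.floor(rng.random(n) * (L - ins + 1)).astype(np.int64)
        all_ci.append(np.full(n, ci, dtype=np.int32))
        all_fs.append(fs)
        all_ins.append(ins)
    chrom_idx = np.concatenate(all_ci) if all_ci else np.empty(0, np.int32)
    frag_start = np.concatenate(all_fs) if all_fs else np.empty(0, np.int64)
    insert = np.concatenate(all_ins) if all_ins else np.empty(0, np.int64)
    n = len(frag_start)
    r1_is_left = rng.random(n) < 0.5

    seq_left = np.empty((n, rl), dtype=np.uint8)
    seq_right = np.empty((n, rl), dtype=np.uint8)
    offsets = np.arange(rl)
    for ci, chrom in enumerate(chroms):
        sel = chrom_idx == ci
        if not sel.any():
            continue
        arr = genome[chrom]
        ls = frag_start[sel]
        rs = frag_start[sel] + insert[sel] - rl
        seq_left[sel] = arr[ls[:, None] + offsets]
        seq_right[sel] = arr[rs[:, None] + offsets]

    if profile.base_error_rate > 0:
        for seqs in (seq_left, seq_right):
            hit = rng.random(seqs.shape) < profile.base_error_rate
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()))
                seqs[hit] = _BASES[(_BASE_INDEX[seqs[hit]] + shift) % 4]

    return ReadSet(
        profile, chroms, chrom_idx, frag_start, insert.astype(np.int32),
        r1_is_left, seq_left, seq_right,
    )


# ---------------------------------------------------------------------------
# Ideal alignments
# ---------------------------------------------------------------------------


def _lift(parts_out: list, blocks_dstart, blocks_dend, blocks_chrom, blocks_rstart,
          s: int, e: int, min_segment: int) -> None:
    """Append (qoff, length, ref_chrom, ref_pos) parts for derived [s, e)."""
    i = int(np.searchsorted(blocks_dend, s, side="right"))
    while i < len(blocks_dend) and blocks_dstart[i] < e:
        ps = max(s, int(blocks_dstart[i]))
        pe = min(e, int(blocks_dend[i]))
        if pe - ps >= min_segment:
            parts_out.append(
                (ps - s, pe - ps, blocks_chrom[i],
                 int(blocks_rstart[i]) + ps - int(blocks_dstart[i]))
            )
        i += 1


def _cigar(qoff: int, length: int, rl: int) -> str:
    pre = f"{qoff}S" if qoff else ""
    post = f"{rl - qoff - length}S" if rl - qoff - length else ""
    return f"{pre}{length}M{post}"


def emit_ideal_alignments(
    reads: ReadSet,
    blocks: dict[str, list[Block]] | None,
    reference: dict[str, np.ndarray] | dict[str, int],
    path: str | Path,
    mapq: int = 60,
    min_segment: int = 20,
) -> None:
    """Write the SAM alignments the reads would have on the reference.

    Read origins in the derived genome are lifted through ``blocks``
    (pass None when reads come from the reference itself).  Reads wholly
    inside one block become plain records; reads crossing a block
    boundary become soft-clipped split records with SA tags; mates
    landing on lifted positions farther apart than the insert model
    allows become discordant pairs.  Origins that lift to no segment of
    at least ``min_segment`` bp are emitted unmapped.  Output is
    coordinate-sorted SAM text.
    """
    ref_lengths = {
        c: (len(v) if hasattr(v, "__len__") else int(v)) for c, v in reference.items()
    }
    ref_order = {c: i for i, c in enumerate(ref_lengths)}
    rl = reads.profile.read_length
    proper_cut = reads.profile.insert_mean + 4 * reads.profile.insert_sd
    if blocks is None:
        blocks = {c: [Block(0, n, c, 0)] for c, n in ref_lengths.items()}

    barr = {}
    for chrom, blist in blocks.items():
        barr[chrom] = (
            np.array([b.dstart for b in blist], dtype=np.int64),
            np.array([b.dend for b in blist], dtype=np.int64),
            [b.ref_chrom for b in blist],
            np.array([b.ref_start for b in blist], dtype=np.int64),
        )

    out: list[tuple[int, int, str]] = []
    unmapped: list[str] = []
    qual = "I" * rl

    for i in range(reads.n_pairs):
        dchrom = reads.chrom_names[reads.chrom_idx[i]]
        bd, be, bc, br = barr[dchrom]
        fs = int(reads.frag_start[i])
        ins = int(reads.insert[i])
        name = reads.name(i)
        mates = []
        for side, (s, seq) in enumerate(
            [(fs, reads.seq_left[i]), (fs + ins - rl, reads.seq_right[i])]
        ):
            parts: list[tuple[int, int, str, int]] = []
            _lift(parts, bd, be, bc, br, s, s + rl, min_segment)
            mates.append((parts, seq, side))

        primaries = []
        for parts, seq, side in mates:
            if not parts:
                primaries.append(None)
            else:
                primaries.append(max(parts, key=lambda p: p[1]))

        for (parts, seq, side), primary, other_primary in (
            (mates[0], primaries[0], primaries[1]),
            (mates[1], primaries[1], primaries[0]),
        ):
            strand = side  # 0 = left/'+', 1 = right/'-'
            flag_base = 1 | (64 if (side == 0) == bool(reads.r1_is_left[i]) else 128)
            if strand == 1:
                flag_base |= 16
            if other_primary is None:
                flag_base |= 8
            elif side == 0:
                flag_base |= 32  # right mate is always '-'
            if primary is None:
                seqs = seq.tobytes().decode()
                unmapped.append(
                    f"{name}\t{flag_base | 4}\t*\t0\t0\t*\t*\t0\t0\t{seqs}\t{qual}"
                )
                continue
            # mate / template fields from the two primary segments
            if other_primary is not None:
                ochrom, opos = other_primary[2], other_primary[3]
                rnext = "=" if ochrom == primary[2] else ochrom
                pnext = opos + 1
                if ochrom == primary[2]:
                    left = min(primary[3], opos)
                    right = max(primary[3] + primary[1], opos + other_primary[1])
                    span = right - left
                    tlen = span if primary[3] <= opos else -span
                    if (
                        span <= proper_cut
                        and (primary[3] <= opos) == (strand == 0)
                    ):
                        flag_base |= 2
                else:
                    tlen = 0
            else:
                rnext, pnext, tlen = "*", 0, 0
            seqs = seq.tobytes().decode()
            mc = _cigar(other_primary[0], other_primary[1], rl) if other_primary else None
            others = [p for p in parts if p is not primary]
            for part in parts:
                qoff, length, pchrom, ppos = part
                flag = flag_base | (0 if part is primary else 2048)
                cigar = _cigar(qoff, length, rl)
                tags = [f"MQ:i:{mapq}"]
                if mc:
                    tags.append(f"MC:Z:{mc}")
                sa_parts = [p for p in parts if p is not part]
                if sa_parts:
                    sa = "".join(
                        f"{pc},{pp + 1},{'-' if strand else '+'},"
                        f"{_cigar(qo, ln, rl)},{mapq},0;"
                        for qo, ln, pc, pp in sa_parts
                    )
                    tags.append(f"SA:Z:{sa}")
                line = (
                    f"{name}\t{flag}\t{pchrom}\t{ppos + 1}\t{mapq}\t{cigar}"
                    f"\t{rnext}\t{pnext}\t{tlen}\t{seqs}\t{qual}\t"
                    + "\t".join(tags)
                )
                out.append((ref_order[pchrom], ppos, line))

    out.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, n in ref_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{n}\n")
        for _, _, line in out:
            fh.write(line + "\n")
        for line in unmapped:
            fh.write(line + "\n")


def drop_pairs_overlapping(reads: ReadSet, chrom: str, start: int, end: int) -> ReadSet:
    """A copy of ``reads`` without pairs whose fragment touches
    [start, end) on ``chrom`` (derived-genome coordinates) — used to
    manufacture a guaranteed zero-coverage region."""
    ci = reads.chrom_names.index(chrom)
    frag_end = reads.frag_start + reads.insert
    keep = ~(
        (reads.chrom_idx == ci)
        & (reads.frag_start < end)
        & (frag_end > start)
    )
    return ReadSet(
        reads.profile, reads.chrom_names, reads.chrom_idx[keep],
        reads.frag_start[keep], reads.insert[keep], reads.r1_is_left[keep],
        reads.seq_left[keep], reads.seq_right[keep],
    )


def derived_interval_of_insertion(
    truth: SimulationTruth, ins: PlantedInsertion
) -> tuple[str, int, int]:
    """(derived chrom, start, end) of the inserted copy planted by ``ins``."""
    for chrom, blist in truth.blocks.items():
        if chrom != ins.chrom:
            continue
        for b in blist:
            if (
                b.ref_chrom == ins.source_chrom
                and b.ref_start == ins.source_start
                and b.dend - b.dstart == ins.length
            ):
                return chrom, b.dstart, b.dend
    raise KeyError(f"no derived block found for insertion of {ins.te_id}")


# ---------------------------------------------------------------------------
# Evaluation against truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CallMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        total = self.tp + self.fn
        return self.tp / total if total else 1.0

    @property
    def fdr(self) -> float:
        called = self.tp + self.fp
        return self.fp / called if called else 0.0


@dataclass(frozen=True)
class EvaluationResult:
    insertion: CallMetrics
    absence: CallMetrics


def _greedy_match(calls, truths, distance) -> tuple[int, int, int]:
    pairs = []
    for ci, call in enumerate(calls):
        for ti, t in enumerate(truths):
            d = distance(call, t)
            if d is not None:
                pairs.append((d, ci, ti))
    pairs.sort(key=lambda x: x[0])
    used_c: set[int] = set()
    used_t: set[int] = set()
    for d, ci, ti in pairs:
        if ci not in used_c and ti not in used_t:
            used_c.add(ci)
            used_t.add(ti)
    tp = len(used_t)
    return tp, len(calls) - len(used_c), len(truths) - tp


def evaluate_calls(
    calls: Iterable[VariantRecord],
    truth: SimulationTruth,
    breakpoint_tolerance_bp: int = 100,
    annotation: Sequence[TEAnnotation] | None = None,
) -> EvaluationResult:
    """Greedy one-to-one matching of calls to planted events.

    An insertion call matches a planted insertion when the breakpoint
    interval lies within tolerance of the planted position and the
    called TE family equals the donor family.  An absence call matches a
    planted deletion within tolerance.  Cut-paste donor sites are
    ambiguous under read mapping — the moved copy's reads still map back
    to the donor locus, so its depth signature is not that of a clean
    deletion — and calls landing on them are excluded from both the TP
    and FP tallies.  Sensitivity = TP/(TP+FN); FDR = FP/(TP+FP), 0 when
    nothing is called.
    """
    calls = list(calls)
    fam_map: dict[str, str] = {}
    if annotation is not None:
        fam_map = {t.te_id: t.family for t in annotation}
    else:
        for ev in truth.insertions:
            fam_map[ev.te_id] = ev.family
        for ev in truth.excised:
            fam_map[ev.te_id] = ev.family

    pres = [c for c in calls if c.variant_type == "presence"]
    abse = [c for c in calls if c.variant_type == "absence"]

    def ins_distance(call: VariantRecord, t: PlantedInsertion):
        if call.chrom != t.chrom:
            return None
        d = max(call.start - t.position, t.position - call.end, 0)
        if d > breakpoint_tolerance_bp:
            return None
        families = {fam_map.get(te, "?") for te in call.te_ids}
        if fam_map and t.family not in families:
            return None
        return d

    def abs_distance(call: VariantRecord, t: PlantedDeletion):
        if call.chrom != t.chrom:
            return None
        d = max(call.start - t.end, t.start - call.end, 0)
        return d if d <= breakpoint_tolerance_bp else None

    # absence calls at cut-paste donor sites are neither TPs nor FPs
    abse = [
        c for c in abse
        if not any(abs_distance(c, t) is not None for t in truth.cut_paste_sources)
    ]
    return EvaluationResult(
        insertion=CallMetrics(*_greedy_match(pres, truth.insertions, ins_distance)),
        absence=CallMetrics(*_greedy_match(abse, truth.deletions, abs_distance)),
    )


# ---------------------------------------------------------------------------
# Population-scale matrix generators
# ---------------------------------------------------------------------------


def simulate_genotype_matrix(
    n_variants: int,
    n_accessions: int,
    seed: int = 0,
    freqs: np.ndarray | None = None,
    na_rate: float = 0.02,
    prefix: str = "v",
) -> pd.DataFrame:
    """Random presence/absence genotype matrix (1/0/NaN).

    Per-variant presence frequencies default to Beta(0.4, 2.5) draws,
    which skews toward rare variants the way a natural population's TE
    allele-frequency spectrum does.
    """
    rng = np.random.default_rng(seed)
    if freqs is None:
        freqs = rng.beta(0.4, 2.5, size=n_variants)
    freqs = np.asarray(freqs, dtype=float)
    geno = (rng.random((n_variants, n_accessions)) < freqs[:, None]).astype(float)
    if na_rate > 0:
        geno[rng.random(geno.shape) < na_rate] = np.nan
    return pd.DataFrame(
        geno,
        index=[f"{prefix}{i + 1:05d}" for i in range(n_variants)],
        columns=[f"acc{j + 1:04d}" for j in range(n_accessions)],
    )


def simulate_ld_panel(
    n_accessions: int = 187,
    n_snps: int = 600,
    mode: str = "high",
    seed: int = 0,
    flip_rate: float = 0.002,
    te_noise: float = 0.01,
) -> tuple[pd.Series, pd.DataFrame, np.ndarray, int]:
    """A block of locally-correlated SNPs plus a TE genotype vector.

    SNP i+1 copies SNP i with per-accession flips at ``flip_rate``, so
    nearby SNPs are in strong LD and correlation decays with distance.
    The default flip rate keeps the focal marker correlated across a
    large share of a 600-SNP window, the long-haplotype structure of a
    highly selfing population.  ``mode='high'`` makes the TE a
    near-copy of the central SNP (strong TE-SNP linkage); ``mode='low'``
    draws it independently.  Returns (te, snps, snp_positions, te_position).
    """
    rng = np.random.default_rng(seed)
    snps = np.empty((n_snps, n_accessions))
    snps[0] = rng.random(n_accessions) < 0.5
    for i in range(1, n_snps):
        flip = rng.random(n_accessions) < flip_rate
        snps[i] = np.where(flip, 1 - snps[i - 1], snps[i - 1])
    positions = np.sort(rng.choice(np.arange(1, 600_000), size=n_snps, replace=False))
    mid = n_snps // 2
    te_pos = int((positions[mid - 1] + positions[mid]) // 2)
    if mode == "high":
        flip = rng.random(n_accessions) < te_noise
        te = np.where(flip, 1 - snps[mid], snps[mid])
    elif mode == "low":
        te = (rng.random(n_accessions) < 0.3).astype(float)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cols = [f"acc{j + 1:04d}" for j in range(n_accessions)]
    snp_df = pd.DataFrame(
        snps, index=[f"snp{i + 1:05d}" for i in range(n_snps)], columns=cols
    )
    return pd.Series(te, index=cols, name="te"), snp_df, positions, te_pos


def simulate_burden_phenotypes(
    n_accessions: int = 200,
    n_phenotypes: int = 500,
    mode: str = "u",
    carriers_low: int = 1,
    carriers_high: int = 6,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Phenotypes plus rare carriers, optionally enriched in the extremes.

    ``mode='u'`` draws each rare variant's carriers with probability
    rising quadratically toward the phenotype extremes (a graded
    U-shaped burden, the shape a phenotype-perturbing rare allele
    produces when its effect size varies); ``mode='null'`` draws
    carriers uniformly.  Returns (phenotypes, rare genotypes,
    phenotype -> variant ids map).
    """
    rng = np.random.default_rng(seed)
    cols = [f"acc{j + 1:04d}" for j in range(n_accessions)]
    values = rng.normal(size=(n_phenotypes, n_accessions))
    pheno = pd.DataFrame(
        values, index=[f"ph{i + 1:05d}" for i in range(n_phenotypes)], columns=cols
    )
    geno = np.zeros((n_phenotypes, n_accessions))
    mapping: dict[str, list[str]] = {}
    var_ids = []
    for i, ph in enumerate(pheno.index):
        k = int(rng.integers(carriers_low, carriers_high + 1))
        if mode == "u":
            ranks = np.argsort(np.argsort(values[i]))
            x = ranks / (n_accessions - 1)
            w = (x - 0.5) ** 2 + 0.005
            carriers = rng.choice(
                n_accessions, size=k, replace=False, p=w / w.sum()
            )
        elif mode == "null":
            carriers = rng.choice(n_accessions, size=k, replace=False)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        geno[i, carriers] = 1.0
        vid = f"rv{i + 1:05d}"
        var_ids.append(vid)
        mapping[ph] = [vid]
    geno_df = pd.DataFrame(geno, index=var_ids, columns=cols)
    return pheno, geno_df, mapping


def simulate_methylation_panel(
    genotypes: pd.DataFrame,
    n_dmrs: int = 100,
    planted: dict[str, str] | None = None,
    effect: float = 0.6,
    noise_sd: float = 0.08,
    na_rate: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """DMR methylation-level matrix with optional planted TE associations.

    ``planted`` maps dmr_id -> variant_id; a planted DMR's methylation
    tracks the variant genotype (baseline + effect * genotype + noise,
    clipped to [0, 1]); all other DMRs are genotype-independent noise.
    """
    rng = np.random.default_rng(seed)
    cols = genotypes.columns
    dmr_ids = [f"dmr{i + 1:05d}" for i in range(n_dmrs)]
    base = rng.uniform(0.1, 0.3, size=n_dmrs)
    meth = base[:, None] + rng.normal(0, noise_sd, size=(n_dmrs, len(cols)))
    df = pd.DataFrame(meth, index=dmr_ids, columns=cols)
    if planted:
        for dmr_id, var_id in planted.items():
            g = genotypes.loc[var_id].to_numpy(dtype=float)
            g = np.nan_to_num(g, nan=0.0)
            df.loc[dmr_id] = (
                base[dmr_ids.index(dmr_id)]
                + effect * g
                + rng.normal(0, noise_sd, size=len(cols))
            )
    arr = df.to_numpy()
    np.clip(arr, 0.0, 1.0, out=arr)
    if na_rate > 0:
        arr[rng.random(arr.shape) < na_rate] = np.nan
    return pd.DataFrame(arr, index=dmr_ids, columns=cols)
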