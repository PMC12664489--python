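"""Genomic interval data model, interval algebra, and flat-file readers/writers.

Every region handled by the pipeline -- H3K27ac peaks, regulatory elements,
pooled domains, shade controls, cistrome binding regions -- is a
:class:`GenomicInterval`.  All coordinates are 0-based half-open (the BED
convention); the single place where 1-based arithmetic occurs is GTF import,
where the TSS of a gene spanning ``start..end`` (1-based inclusive) is
``start - 1`` on the ``+`` strand and ``end - 1`` on ``-``.

Strand is carried on gene annotations but ignored by interval algebra:
H3K27ac peaks and the domains pooled from them are unstranded.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GenomeTable",
    "GeneAnnotation",
    "merge_intervals",
    "distance_to_nearest",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
    "read_counts",
    "write_counts",
    "read_chrom_sizes",
    "write_chrom_sizes",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on ``chrom``.

    ``name`` and ``score`` are optional payload (BED columns 4 and 5).
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:[{self.start},{self.end})")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:[{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class GenomeTable(Mapping[str, int]):
    """Chromosome name -> length (bp).  Defines the bounds used for clipping."""

    def __init__(self, sizes: Mapping[str, int]):
        sizes = dict(sizes)
        for chrom, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        self._sizes = sizes

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __iter__(self):
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return f"GenomeTable({self._sizes!r})"

    def total_length(self) -> int:
        return sum(self._sizes.values())

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:[{iv.start},{iv.end}) exceeds chromosome "
                f"length {self._sizes[iv.chrom]}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to the single coordinate the pipeline needs: its TSS."""

    gene_id: str
    chrom: str
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def _group_by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def merge_intervals(
    intervals: Sequence[GenomicInterval], merge_distance: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is at most ``merge_distance`` bp.

    Two intervals are merged when ``next.start - prev.end <= merge_distance``,
    transitively.  With ``merge_distance == 0`` only overlapping or bookended
    intervals merge.  Output is sorted by (chrom, start) and carries no
    name/score payload.
    """
    if merge_distance < 0:
        raise ValueError(f"merge_distance must be >= 0, got {merge_distance}")
    merged: list[GenomicInterval] = []
    grouped = _group_by_chrom(intervals)
    for chrom in sorted(grouped):
        ivs = sorted(grouped[chrom], key=lambda iv: (iv.start, iv.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_e <= merge_distance:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def distance_to_nearest(
    queries: Sequence[tuple[str, int]],
    targets: Sequence[tuple[str, int, str]],
) -> list[tuple[int | None, str | None]]:
    """Nearest-target distance for each query point.

    ``queries`` are ``(chrom, position)``; ``targets`` are
    ``(chrom, position, target_id)``.  Returns one ``(distance, target_id)``
    pair per query.  Equidistant ties break toward the target at the smaller
    coordinate; queries on a chromosome with no target get ``(None, None)``.
    """
    if len(targets) == 0:
        raise ValueError("distance_to_nearest requires a nonempty target set")
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, pos, tid in targets:
        by_chrom.setdefault(chrom, []).append((pos, tid))
    index: dict[str, tuple[np.ndarray, list[str]]] = {}
    for chrom, items in by_chrom.items():
        items.sort(key=lambda t: (t[0], t[1]))
        index[chrom] = (np.asarray([p for p, _ in items]), [t for _, t in items])

    results: list[tuple[int | None, str | None]] = []
    for chrom, pos in queries:
        if chrom not in index:
            results.append((None, None))
            continue
        positions, ids = index[chrom]
        j = int(np.searchsorted(positions, pos))
        best: tuple[int, int] | None = None  # (distance, index)
        if j > 0:
            best = (pos - int(positions[j - 1]), j - 1)
        if j < len(positions):
            d = int(positions[j]) - pos
            # strict <: on a tie the left (smaller-coordinate) target wins
            if best is None or d < best[0]:
                best = (d, j)
        assert best is not None
        results.append((best[0], ids[best[1]]))
    return results


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, genome: GenomeTable | None = None) -> list[GenomicInterval]:
    """Read a BED3/BED5/BED6 file into intervals (0-based half-open)."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric score") from exc
            try:
                iv = GenomicInterval(fields[0], start, end, name, score)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if genome is not None:
                try:
                    genome.validate_interval(iv)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            if iv.score is None:
                score = "."
            else:
                score = repr(iv.score) if iv.score != int(iv.score) else str(int(iv.score))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")


def _parse_gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if " " in part:
            key, _, value = part.partition(" ")
            out[key] = value.strip().strip('"')
    return out


def read_gene_table(path: str | Path, genome: GenomeTable | None = None) -> list[GeneAnnotation]:
    """Read gene annotation from GTF (gene features) or a 4-column TSV.

    The TSV dialect is ``gene_id<TAB>chrom<TAB>strand<TAB>tss`` with an
    optional header row; TSV positions are already 0-based.  GTF coordinates
    are 1-based inclusive and are converted here.
    """
    path = Path(path)
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 9 and fields[3].isdigit() and fields[4].isdigit():
                if fields[2] != "gene":
                    continue
                attrs = _parse_gtf_attributes(fields[8])
                gene_id = attrs.get("gene_id")
                if gene_id is None:
                    raise ValueError(f"{path}:{lineno}: GTF gene record without gene_id")
                chrom, strand = fields[0], fields[6]
                start1, end1 = int(fields[3]), int(fields[4])
                tss = start1 - 1 if strand == "+" else end1 - 1
            elif len(fields) == 4:
                if lineno == 1 and not fields[3].lstrip("-").isdigit():
                    continue  # header row
                gene_id, chrom, strand = fields[0], fields[1], fields[2]
                try:
                    tss = int(fields[3])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-integer TSS") from exc
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected a 9-field GTF line or 4-field TSV line"
                )
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            try:
                gene = GeneAnnotation(gene_id, chrom, strand, tss)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if genome is not None:
                if chrom not in genome:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if tss >= genome[chrom]:
                    raise ValueError(f"{path}:{lineno}: TSS beyond chromosome end")
            genes.append(gene)
    return genes


def write_gene_table(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\n")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample count matrix (TSV, header row, feature ids in col 1)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns")
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        bad = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise ValueError(f"{path}: non-numeric sample columns {bad}")
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_chrom_sizes(path: str | Path) -> GenomeTable:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer length") from exc
    return GenomeTable(sizes)


def write_chrom_sizes(genome: GenomeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f"{chrom}\t{genome[chrom]}\n")
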