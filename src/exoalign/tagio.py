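"""Reading mapped-tag data and region lists.

Tags are reduced to their 5'-most genomic base and strand; everything
downstream operates on per-base, strand-separated 5' tag counts.
Genomic coordinates are 1-based inclusive internally; BED input is
converted from 0-based half-open on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

__all__ = [
    "TagLibrary",
    "Region",
    "RegionSet",
    "read_tags",
    "read_regions",
    "extract_window",
    "write_tags_sam",
    "write_tags_tsv",
]


class TagIOError(RuntimeError):
    """Fatal problem with a tag or region input file."""


@dataclass
class TagLibrary:
    """Per-chromosome, strand-separated 5' tag positions for one experiment.

    ``tags[chrom]`` is a pair of sorted int arrays ``(plus, minus)`` of
    1-based positions of tag 5' ends on each strand.
    """

    name: str
    tags: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def total_tag_count(self) -> int:
        return sum(len(p) + len(m) for p, m in self.tags.values())

    def add(self, chrom: str, positions_plus, positions_minus) -> None:
        p = np.sort(np.asarray(positions_plus, dtype=np.int64))
        m = np.sort(np.asarray(positions_minus, dtype=np.int64))
        if (len(p) and p[0] < 1) or (len(m) and m[0] < 1):
            raise TagIOError(f"{self.name}: tag position < 1 on {chrom}")
        self.tags[chrom] = (p, m)

    def chrom_tags(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self.tags.get(chrom, (empty, empty))


@dataclass(frozen=True)
class Region:
    chrom: str
    anchor: int  # 1-based bp
    strand: str  # '+' or '-'
    id: str


@dataclass
class RegionSet:
    regions: list[Region]
    window_size: int

    def __iter__(self):
        return iter(self.regions)

    def __len__(self):
        return len(self.regions)


def _tag_position(read: pysam.AlignedSegment) -> tuple[int, str]:
    # 5' end: leftmost base for forward reads, rightmost for reverse reads.
    if read.is_reverse:
        return read.reference_end, "-"  # reference_end is 0-based exclusive == 1-based last
    return read.reference_start + 1, "+"


def read_tags(
    alignment_file: str | os.PathLike,
    min_mapq: int = 5,
    name: str | None = None,
    include_r2: bool = False,
    deduplicate: bool = False,
) -> TagLibrary:
    """Load tag 5' positions from a SAM/BAM file or a tag TSV.

    Each retained read contributes one tag at its 5'-most genomic base on
    its strand. Unmapped, secondary and supplementary reads are skipped, as
    are reads with MAPQ below ``min_mapq``. For paired-end data only R1
    contributes unless ``include_r2`` is set. ``deduplicate`` collapses tags
    sharing an identical (chrom, position, strand); off by default since
    duplicate marking is normally done upstream.
    """
    path = os.fspath(alignment_file)
    if not os.path.exists(path):
        raise TagIOError(f"tag file not found: {path}")
    if name is None:
        name = os.path.basename(path).rsplit(".", 1)[0]
    if path.endswith((".tsv", ".txt", ".tags")):
        return _read_tags_tsv(path, name)

    per_chrom: dict[str, tuple[list[int], list[int]]] = {}
    lengths: dict[str, int] = {}
    try:
        mode = "rb" if path.endswith(".bam") else "r"
        af = pysam.AlignmentFile(path, mode, check_sq=False)
    except (OSError, ValueError) as exc:
        raise TagIOError(f"cannot open alignment file {path}: {exc}") from exc
    with af:
        for ref, ln in zip(af.references or (), af.lengths or ()):
            lengths[ref] = ln
        n = 0
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.is_paired and read.is_read2 and not include_r2:
                continue
            pos, strand = _tag_position(read)
            chrom = read.reference_name
            bucket = per_chrom.setdefault(chrom, ([], []))
            bucket[0 if strand == "+" else 1].append(pos)
            n += 1
    if n == 0:
        raise TagIOError(f"no tags retained from {path} (min_mapq={min_mapq})")
    lib = TagLibrary(name=name, chrom_lengths=lengths)
    for chrom, (plus, minus) in per_chrom.items():
        if deduplicate:
            plus, minus = sorted(set(plus)), sorted(set(minus))
        lib.add(chrom, plus, minus)
    return lib


def _read_tags_tsv(path: str, name: str) -> TagLibrary:
    """Tag TSV format: chrom <TAB> position(1-based) <TAB> strand, one tag per line."""
    per_chrom: dict[str, tuple[list[int], list[int]]] = {}
    n = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise TagIOError(f"{path}:{line_no}: expected 3 columns")
            chrom, pos, strand = parts[0], int(parts[1]), parts[2]
            if strand not in "+-":
                raise TagIOError(f"{path}:{line_no}: bad strand {strand!r}")
            bucket = per_chrom.setdefault(chrom, ([], []))
            bucket[0 if strand == "+" else 1].append(pos)
            n += 1
    if n == 0:
        raise TagIOError(f"no tags in {path}")
    lib = TagLibrary(name=name)
    for chrom, (plus, minus) in per_chrom.items():
        lib.add(chrom, plus, minus)
    return lib


def write_tags_tsv(lib: TagLibrary, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(lib.tags):
            plus, minus = lib.tags[chrom]
            for p in plus:
                fh.write(f"{chrom}\t{p}\t+\n")
            for m in minus:
                fh.write(f"{chrom}\t{m}\t-\n")


def write_tags_sam(
    lib: TagLibrary, path: str | os.PathLike, chrom_lengths: dict[str, int], read_length: int = 36
) -> None:
    """Write tags as single-end reads in a plain-text SAM file.

    Each tag becomes a fully matched ``read_length`` bp read whose 5' end
    sits at the tag position; reading the file back with :func:`read_tags`
    recovers the library exactly.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in sorted(chrom_lengths)],
    }
    with pysam.AlignmentFile(os.fspath(path), "wh", header=header) as out:
        i = 0
        for chrom in sorted(lib.tags):
            tid = out.get_tid(chrom)
            plus, minus = lib.tags[chrom]
            records = sorted(
                [(int(p), False) for p in plus] + [(int(m) - read_length + 1, True) for m in minus]
            )
            for start, rev in records:
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"t{i}"
                a.reference_id = tid
                a.reference_start = max(0, start - 1)
                a.mapping_quality = 42
                a.cigarstring = f"{read_length}M"
                a.query_sequence = "N" * read_length
                a.flag = 16 if rev else 0
                out.write(a)
                i += 1


def read_regions(path: str | os.PathLike, window_size: int) -> RegionSet:
    """Read regions from 6-column BED (anchor = interval midpoint) or from a
    ``chrom:position:strand`` text list (anchor = position, 1-based)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise TagIOError(f"regions file not found: {path}")
    regions: list[Region] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if ":" in line and "\t" not in line:
                parts = line.split(":")
                if len(parts) != 3 or parts[2] not in "+-":
                    raise TagIOError(f"{path}:{line_no}: expected chrom:position:strand")
                chrom, anchor, strand = parts[0], int(parts[1]), parts[2]
                rid = f"{chrom}:{anchor}:{strand}"
            else:
                parts = line.split("\t")
                if len(parts) < 3:
                    raise TagIOError(f"{path}:{line_no}: not a BED line")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                rid = parts[3] if len(parts) > 3 and parts[3] != "." else f"{chrom}:{start}-{end}"
                strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
                # midpoint of the 0-based half-open interval, converted to 1-based
                anchor = start + (end - start) // 2 + 1
            regions.append(Region(chrom=chrom, anchor=anchor, strand=strand, id=rid))
    if not regions:
        raise TagIOError(f"no regions in {path}")
    return RegionSet(regions=regions, window_size=window_size)


def window_bounds(region: Region, L: int) -> tuple[int, int]:
    """1-based inclusive window [anchor - L/2, anchor + L/2 - 1]."""
    start = region.anchor - L // 2
    return start, start + L - 1


def extract_window(tags: TagLibrary, region: Region, L: int) -> np.ndarray:
    """Per-base strand-separated tag counts in the length-``L`` window
    centred on the region anchor.

    Returns a ``(2, L)`` float array: row 0 counts + strand ("Watson") tags
    per base, row 1 counts - strand ("Crick") tags. Minus-strand regions are
    reversed and strand-swapped so all regions share one orientation.
    """
    start, end = window_bounds(region, L)
    if start < 1:
        raise TagIOError(f"window for region {region.id} runs off the chromosome start")
    chrom_len = tags.chrom_lengths.get(region.chrom)
    if chrom_len is not None and end > chrom_len:
        raise TagIOError(f"window for region {region.id} runs off the end of {region.chrom}")
    plus, minus = tags.chrom_tags(region.chrom)
    out = np.zeros((2, L), dtype=np.float64)
    for row, arr in ((0, plus), (1, minus)):
        lo, hi = np.searchsorted(arr, start), np.searchsorted(arr, end, side="right")
        if hi > lo:
            np.add.at(out[row], arr[lo:hi] - start, 1.0)
    if region.strand == "-":
        out = out[::-1, ::-1].copy()
    return out
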