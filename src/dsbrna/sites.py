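"""Genome model for AsiSI restriction-site analysis.

AsiSI recognises the palindromic 8-mer ``GCGATCGC`` and cleaves
``GCGAT^CGC``, leaving a 2-nt 3' overhang on the ``AT`` dinucleotide.
This module locates recognition sites in a genome, defines the cut
geometry used as the origin of all site-anchored profiles, builds the
binned analysis windows around each cut, and loads externally annotated
cut-site lists (e.g. the canonical set of 99 sites cut in cells, split
25 HR / 25 NHEJ / 49 unspecified by preferential repair pathway).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

ASISI_MOTIF = "GCGATCGC"
#: offset of the cut anchor (profile origin) within the motif
CUT_OFFSET = 4
#: half-open interval of the 2-nt 3' overhang within the motif
OVERHANG_OFFSETS = (3, 5)

REPAIR_CLASSES = ("HR", "NHEJ", "unspecified", "uncut")

#: canonical composition of the annotated cut-site list
STRICT_TOTAL = 99
STRICT_COMPOSITION = {"HR": 25, "NHEJ": 25, "unspecified": 49}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


class SequenceAlphabetError(ValueError):
    """A genome sequence contains characters outside A/C/G/T/N."""


class SiteAnnotationError(ValueError):
    """A cut-site annotation file is malformed or fails validation."""


class WindowGeometryError(ValueError):
    """A requested analysis window is inconsistent with the chromosome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicSite:
    """A recognition/cut site with its cut geometry.

    ``cut_anchor`` is the single coordinate used as the origin ("0") of
    every site-anchored profile; ``overhang`` is the half-open interval
    of the 2-nt 3' overhang left by cleavage.
    """

    chrom: str
    motif_start: int
    cut_anchor: int
    overhang: tuple[int, int]
    repair_class: str = "uncut"
    tss_distance: int | None = None
    site_id: str | None = None

    def __post_init__(self) -> None:
        o0, o1 = self.overhang
        if o1 - o0 != 2:
            raise ValueError(f"overhang must span 2 nt, got {self.overhang}")
        if not (self.motif_start <= o0 and o1 <= self.motif_start + 8):
            raise ValueError("overhang must lie within the 8-mer motif")
        if not (o0 <= self.cut_anchor < o1):
            raise ValueError("cut_anchor must lie inside the overhang")
        if self.repair_class not in REPAIR_CLASSES:
            raise ValueError(
                f"repair_class {self.repair_class!r} not in {REPAIR_CLASSES}"
            )

    @property
    def name(self) -> str:
        return self.site_id or f"{self.chrom}:{self.motif_start}"


def site_at(chrom: str, motif_start: int, repair_class: str = "uncut",
            **kw) -> GenomicSite:
    """Build a :class:`GenomicSite` from a motif start using AsiSI geometry."""
    return GenomicSite(
        chrom=chrom,
        motif_start=motif_start,
        cut_anchor=motif_start + CUT_OFFSET,
        overhang=(motif_start + OVERHANG_OFFSETS[0],
                  motif_start + OVERHANG_OFFSETS[1]),
        repair_class=repair_class,
        **kw,
    )


@dataclass(frozen=True)
class WindowSpec:
    """Geometry of the binned analysis window around a cut anchor.

    Defaults follow the standard readout: coverage in 10-bp windows
    5 kb either side of each cut site.
    """

    half_width: int = 5000
    bin_size: int = 10

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.bin_size <= 0:
            raise ValueError("half_width and bin_size must be positive")
        if self.half_width % self.bin_size:
            raise ValueError("half_width must be divisible by bin_size")

    @property
    def n_bins_per_side(self) -> int:
        return self.half_width // self.bin_size

    @property
    def n_bins(self) -> int:
        return 2 * self.n_bins_per_side

    def bin_offsets(self):
        """Left edges of every bin, relative to the cut anchor."""
        import numpy as np

        return np.arange(-self.half_width, self.half_width, self.bin_size)


@dataclass(frozen=True)
class WindowBin:
    """One bin of an analysis window, in genomic coordinates."""

    start: int
    end: int
    offset: int  # of the unclipped left edge, relative to cut_anchor
    clipped: bool = False


def scan_recognition_sites(
    genome: Mapping[str, str],
    motif: str = ASISI_MOTIF,
) -> list[GenomicSite]:
    """Find every exact occurrence of a palindromic recognition motif.

    Because the motif is its own reverse complement, a single scan of the
    forward strand is strand-complete. Overlapping occurrences are all
    reported. ``N`` bases never match.

    Parameters
    ----------
    genome
        Mapping of sequence name to DNA string (e.g. a dict or a
        ``pyfaidx.Fasta``; values are ``str()``-able).
    motif
        Recognition 8-mer; must equal its own reverse complement.
    """
    motif = motif.upper()
    if reverse_complement(motif) != motif:
        raise ValueError(f"motif {motif!r} is not palindromic")
    sites: list[GenomicSite] = []
    for chrom in genome:
        seq = str(genome[chrom]).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise SequenceAlphabetError(
                f"sequence {chrom!r} contains non-ACGTN characters: "
                f"{sorted(bad)}"
            )
        pos = seq.find(motif)
        while pos != -1:
            sites.append(site_at(str(chrom), pos))
            pos = seq.find(motif, pos + 1)  # overlapping occurrences too
    return sites


def build_windows(
    site: GenomicSite,
    spec: WindowSpec,
    chrom_length: int,
) -> list[WindowBin]:
    """Tile ``[cut_anchor - half_width, cut_anchor + half_width)`` into bins.

    Bins extending outside ``[0, chrom_length)`` are clipped to the
    chromosome and flagged. Bin offsets are reported relative to the cut
    anchor (negative upstream).
    """
    if chrom_length <= 0:
        raise ValueError("chrom_length must be positive")
    anchor = site.cut_anchor
    if not (0 <= anchor < chrom_length):
        raise WindowGeometryError(
            f"cut_anchor {anchor} outside chromosome of length {chrom_length}"
        )
    bins: list[WindowBin] = []
    for off in range(-spec.half_width, spec.half_width, spec.bin_size):
        start = anchor + off
        end = start + spec.bin_size
        cstart, cend = max(start, 0), min(end, chrom_length)
        bins.append(
            WindowBin(start=cstart, end=cend, offset=off,
                      clipped=(cstart, cend) != (start, end))
        )
    return bins


_CLASS_ALIASES = {
    "HR": "HR",
    "NHEJ": "NHEJ",
    "UNSPECIFIED": "unspecified",
    "UNCUT": "uncut",
    "NONE": "unspecified",
}


def normalize_repair_class(label: str) -> str:
    """Map a free-form repair-class label to the canonical vocabulary.

    Case and surrounding whitespace are ignored: ``"hr "`` -> ``"HR"``.
    """
    key = label.strip().upper()
    try:
        return _CLASS_ALIASES[key]
    except KeyError:
        raise SiteAnnotationError(f"unknown repair class label {label!r}")


def load_site_annotations(
    bed_path: str | Path,
    strict: bool = False,
) -> list[GenomicSite]:
    """Load an annotated cut-site list from BED.

    The BED interval is the 8-mer motif; column 4 carries the repair
    class. With ``strict=True`` the list must contain exactly 99 sites
    split 25 HR / 25 NHEJ / 49 unspecified, the canonical composition of
    the confidently cut site set.
    """
    sites: list[GenomicSite] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SiteAnnotationError(
                    f"{bed_path}:{lineno}: expected >=3 tab-separated "
                    f"columns, got {len(fields)}"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise SiteAnnotationError(
                    f"{bed_path}:{lineno}: non-integer coordinates"
                )
            if end - start != 8:
                raise SiteAnnotationError(
                    f"{bed_path}:{lineno}: motif interval must be 8 bp, "
                    f"got {end - start}"
                )
            repair = "unspecified"
            if len(fields) >= 4 and fields[3].strip():
                try:
                    repair = normalize_repair_class(fields[3])
                except SiteAnnotationError as exc:
                    raise SiteAnnotationError(f"{bed_path}:{lineno}: {exc}")
            sites.append(site_at(chrom, start, repair_class=repair,
                                 site_id=f"site_{lineno}"))
    if not sites:
        warnings.warn(f"{bed_path}: no sites loaded", stacklevel=2)
    if strict:
        counts = {c: 0 for c in STRICT_COMPOSITION}
        for s in sites:
            if s.repair_class in counts:
                counts[s.repair_class] += 1
        if len(sites) != STRICT_TOTAL or counts != STRICT_COMPOSITION:
            raise SiteAnnotationError(
                f"strict validation failed: {len(sites)} sites with class "
                f"counts {counts}; expected {STRICT_TOTAL} split "
                f"{STRICT_COMPOSITION}"
            )
    return sorted(sites, key=lambda s: (s.chrom, s.motif_start))


def write_sites_bed(sites: Iterable[GenomicSite], path: str | Path) -> None:
    """Write sites as BED6 (name=repair_class, score=0, strand='+')."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.motif_start}\t{s.motif_start + 8}\t"
                f"{s.repair_class}\t0\t+\n"
            )


def with_repair_classes(
    sites: Sequence[GenomicSite],
    classes: Sequence[str],
) -> list[GenomicSite]:
    """Return copies of ``sites`` relabelled with ``classes`` (same order)."""
    if len(sites) != len(classes):
        raise ValueError("sites and classes must have equal length")
    return [replace(s, repair_class=normalize_repair_class(c))
            for s, c in zip(sites, classes)]
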