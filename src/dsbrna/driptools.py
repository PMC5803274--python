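"""DRIP-seq stage: fragment reconstruction and DNA:RNA-hybrid profiles.

DRIP (DNA:RNA immunoprecipitation with the S9.6 antibody) enriches
genomic fragments containing RNA:DNA hybrids. Paired-end mates are
extended to the full sequenced fragment (5' end of the most 5' read to
the 3' end of the most 3' mate); interchromosomal pairs and fragments
longer than 2500 bp are discarded. Fragment-base coverage is profiled
around cut sites grouped by preferential repair pathway (HR / NHEJ /
unspecified / uncut), damage enrichment is quantified as a per-bin log2
damaged/undamaged ratio, fine structure is resolved at 1-nt resolution
across the 2-nt cut overhang, and metagene profiles around TSS and TES
stratify genes by transcriptional activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .sites import GenomicSite, WindowSpec

MAX_FRAGMENT_LEN = 2500
#: log2-ratio pseudocount, in normalised units (fragment-bases per million)
RATIO_PSEUDOCOUNT = 1.0

CONDITIONS = ("damaged", "undamaged")


@dataclass(frozen=True, slots=True)
class Fragment:
    """A reconstructed DRIP fragment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    condition: str = "damaged"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.end - self.start <= MAX_FRAGMENT_LEN):
            raise ValueError(
                f"fragment length must be in (0, {MAX_FRAGMENT_LEN}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MateRecord:
    """Minimal paired-alignment record (an alternative to pysam segments)."""

    qname: str
    chrom: str
    start: int
    end: int
    is_read1: bool
    is_paired: bool = True


def _as_mate(rec) -> MateRecord | None:
    """Normalise a pysam AlignedSegment or MateRecord; None if unmapped."""
    if isinstance(rec, MateRecord):
        return rec
    if rec.is_unmapped or rec.reference_name is None:
        return None
    return MateRecord(
        qname=rec.query_name,
        chrom=rec.reference_name,
        start=rec.reference_start,
        end=rec.reference_end,
        is_read1=rec.is_read1,
        is_paired=rec.is_paired,
    )


def reconstruct_fragments(
    records: Iterable,
    condition: str = "damaged",
    sample_id: str = "",
) -> tuple[list[Fragment], dict[str, int]]:
    """Rebuild sequenced fragments from mate pairs.

    Fragment = [min(start of both mates), max(end of both mates)).
    Rejections are tallied by reason: ``unpaired`` (missing mate or not
    flagged paired), ``malformed`` (two mates that are both read1 or
    both read2), ``interchromosomal``, ``too_long`` (>2500 bp).
    """
    tally = {"kept": 0, "unpaired": 0, "malformed": 0,
             "interchromosomal": 0, "too_long": 0}
    by_name: dict[str, list[MateRecord]] = {}
    for rec in records:
        m = _as_mate(rec)
        if m is None:
            continue
        by_name.setdefault(m.qname, []).append(m)
    fragments: list[Fragment] = []
    for qname, mates in by_name.items():
        if len(mates) != 2 or not all(m.is_paired for m in mates):
            tally["unpaired"] += 1
            continue
        a, b = mates
        if a.is_read1 == b.is_read1:
            tally["malformed"] += 1
            continue
        if a.chrom != b.chrom:
            tally["interchromosomal"] += 1
            continue
        start, end = min(a.start, b.start), max(a.end, b.end)
        if end - start > MAX_FRAGMENT_LEN:
            tally["too_long"] += 1
            continue
        fragments.append(Fragment(chrom=a.chrom, start=start, end=end,
                                  condition=condition, sample_id=sample_id))
        tally["kept"] += 1
    return fragments, tally


def fragments_from_sam(path: str | Path, condition: str = "damaged",
                       sample_id: str = "") -> tuple[list[Fragment],
                                                     dict[str, int]]:
    """Reconstruct fragments from a SAM/BAM file of paired alignments."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return reconstruct_fragments(fh, condition=condition,
                                     sample_id=sample_id)


def write_fragments_bed(fragments: Iterable[Fragment],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.condition}\n")


class _FragmentIndex:
    """Per-chromosome start-sorted interval arrays for fast window queries."""

    def __init__(self, fragments: Sequence[Fragment]) -> None:
        per: dict[str, list[tuple[int, int]]] = {}
        for f in fragments:
            per.setdefault(f.chrom, []).append((f.start, f.end))
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in per.items():
            arr = np.array(ivs, dtype=np.int64)
            order = np.argsort(arr[:, 0], kind="stable")
            self.by_chrom[chrom] = (arr[order, 0], arr[order, 1])

    def window_coverage(self, chrom: str, ws: int, we: int) -> np.ndarray:
        """Per-nucleotide fragment-base coverage over [ws, we)."""
        width = we - ws
        cov = np.zeros(width)
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return cov
        starts, ends = entry
        i0 = np.searchsorted(starts, ws - MAX_FRAGMENT_LEN, "left")
        i1 = np.searchsorted(starts, we, "left")
        s, e = starts[i0:i1], ends[i0:i1]
        keep = e > ws
        a = np.clip(s[keep] - ws, 0, width)
        b = np.clip(e[keep] - ws, 0, width)
        delta = np.zeros(width + 1)
        np.add.at(delta, a, 1.0)
        np.add.at(delta, b, -1.0)
        return np.cumsum(delta[:-1])


@dataclass
class EnrichmentProfile:
    """Per-repair-class coverage and damage enrichment around cut anchors.

    ``mean_coverage[cls][condition]`` is the mean over that class's
    sites of binned fragment-base coverage, normalised to fragment-bases
    per million library fragments. ``log2_ratio[cls]`` is the per-bin
    ``log2((damaged + c) / (undamaged + c))`` with pseudocount ``c`` = 1
    normalised unit, so the ratio is finite even in empty bins (and 0
    where both conditions are empty).
    """

    offsets: np.ndarray
    mean_coverage: dict[str, dict[str, np.ndarray]]
    log2_ratio: dict[str, np.ndarray]
    n_sites: dict[str, int]
    spec: WindowSpec


def class_profiles(
    fragments_by_condition: Mapping[str, Sequence[Fragment]],
    sites: Sequence[GenomicSite],
    spec: WindowSpec,
    library_sizes: Mapping[str, int] | None = None,
) -> EnrichmentProfile:
    """Mean binned coverage per repair class and per-bin log2 damage ratio."""
    for cond in CONDITIONS:
        if cond not in fragments_by_condition:
            raise ValueError(f"missing condition {cond!r}")
    lib = {
        cond: (library_sizes[cond] if library_sizes is not None
               else len(fragments_by_condition[cond]))
        for cond in CONDITIONS
    }
    for cond, n in lib.items():
        if n <= 0:
            raise ValueError(f"library size for {cond!r} must be positive")
    classes = sorted({s.repair_class for s in sites})
    offsets = spec.bin_offsets()
    mean_cov: dict[str, dict[str, np.ndarray]] = {c: {} for c in classes}
    n_sites = {c: sum(s.repair_class == c for s in sites) for c in classes}
    for cond in CONDITIONS:
        index = _FragmentIndex(fragments_by_condition[cond])
        sums = {c: np.zeros(spec.n_bins) for c in classes}
        for site in sites:
            cov = index.window_coverage(site.chrom,
                                        site.cut_anchor - spec.half_width,
                                        site.cut_anchor + spec.half_width)
            binned = cov.reshape(spec.n_bins, spec.bin_size).sum(axis=1)
            sums[site.repair_class] += binned
        for c in classes:
            mean_cov[c][cond] = (sums[c] / max(n_sites[c], 1)) * \
                (1e6 / lib[cond])
    ratio = {
        c: np.log2((mean_cov[c]["damaged"] + RATIO_PSEUDOCOUNT)
                   / (mean_cov[c]["undamaged"] + RATIO_PSEUDOCOUNT))
        for c in classes
    }
    return EnrichmentProfile(offsets=offsets, mean_coverage=mean_cov,
                             log2_ratio=ratio, n_sites=n_sites, spec=spec)


@dataclass
class OverhangProfile:
    """1-nt resolution coverage across the cut, summed over sites.

    ``dip_statistic`` = mean coverage over the 2 overhang positions
    divided by mean coverage over the 10 flanking positions on each
    side; 0 when every fragment ends at the cut, ~1 when fragments
    ignore it. NaN if the flanks are empty.
    """

    offsets: np.ndarray
    coverage: np.ndarray
    dip_statistic: float


def overhang_profile(
    fragments: Sequence[Fragment],
    sites: Sequence[GenomicSite],
    radius: int = 50,
) -> OverhangProfile:
    """Per-nucleotide coverage at offsets -radius..+radius from cut anchors.

    The overhang occupies offsets -1 and 0 (the anchor is the second
    overhang base); flanks are offsets -11..-2 and +1..+10.
    """
    if radius < 10:
        raise ValueError("radius must be >= 10")
    index = _FragmentIndex(fragments)
    offsets = np.arange(-radius, radius + 1)
    cov = np.zeros(2 * radius + 1)
    for site in sites:
        cov += index.window_coverage(site.chrom, site.cut_anchor - radius,
                                     site.cut_anchor + radius + 1)
    overhang = cov[radius - 1: radius + 1]          # offsets -1, 0
    flanks = np.concatenate([cov[radius - 11: radius - 1],   # -11..-2
                             cov[radius + 1: radius + 11]])  # +1..+10
    flank_mean = flanks.mean()
    dip = float(overhang.mean() / flank_mean) if flank_mean > 0 else float("nan")
    return OverhangProfile(offsets=offsets, coverage=cov, dip_statistic=dip)


@dataclass
class MetageneProfile:
    """Mean coverage around TSS and TES per transcription stratum."""

    offsets: np.ndarray
    tss: pd.DataFrame  # strata x bins
    tes: pd.DataFrame
    strata_bounds: list[tuple[float, float]]


def metagene_profile(
    fragments: Sequence[Fragment],
    gene_table: pd.DataFrame,
    flank: int = 2000,
    n_strata: int = 4,
    bin_size: int = 50,
    library_size: int | None = None,
) -> MetageneProfile:
    """TSS- and TES-anchored coverage, genes stratified by TPM quantile.

    Orientation is strand-aware (upstream negative): for a minus-strand
    gene the upstream flank maps to higher genomic coordinates. Profiles
    are normalised per million fragments.
    """
    if len(gene_table) < n_strata:
        raise ValueError("fewer genes than strata")
    if flank % bin_size:
        raise ValueError("flank must be divisible by bin_size")
    lib = library_size if library_size is not None else len(fragments)
    if lib <= 0:
        raise ValueError("library size must be positive")
    index = _FragmentIndex(fragments)
    n_bins = 2 * (flank // bin_size)
    offsets = np.arange(-flank, flank, bin_size)
    quantiles = pd.qcut(gene_table["tpm"].rank(method="first"),
                        n_strata, labels=False)
    tss_sum = np.zeros((n_strata, n_bins))
    tes_sum = np.zeros((n_strata, n_bins))
    n_genes = np.zeros(n_strata, dtype=int)
    bounds: dict[int, tuple[float, float]] = {}
    for (_, gene), stratum in zip(gene_table.iterrows(), quantiles):
        strand = str(gene["strand"])
        tss = int(gene["tss"])
        length = int(gene["gene_length"])
        tes = tss + length if strand == "+" else tss - length
        for anchor, acc in ((tss, tss_sum), (tes, tes_sum)):
            cov = index.window_coverage(str(gene["chrom"]), anchor - flank,
                                        anchor + flank)
            if strand == "-":
                cov = cov[::-1]
            acc[stratum] += cov.reshape(n_bins, bin_size).sum(axis=1)
        n_genes[stratum] += 1
        lo, hi = bounds.get(stratum, (np.inf, -np.inf))
        bounds[stratum] = (min(lo, float(gene["tpm"])),
                           max(hi, float(gene["tpm"])))
    scale = (1e6 / lib) / np.maximum(n_genes, 1)[:, None]
    idx = [f"stratum_{i}" for i in range(n_strata)]
    return MetageneProfile(
        offsets=offsets,
        tss=pd.DataFrame(tss_sum * scale, index=idx, columns=offsets),
        tes=pd.DataFrame(tes_sum * scale, index=idx, columns=offsets),
        strata_bounds=[bounds.get(i, (np.nan, np.nan))
                       for i in range(n_strata)],
    )
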