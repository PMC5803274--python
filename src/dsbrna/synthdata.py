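"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here at a reduced,
desk-scale geometry that preserves the statistical structure the
analysis assumes: a genome whose recognition motif occurs only at
planted positions, of which a subset is "cut" and labelled by repair
class in the canonical 25:25:49 proportions; small-RNA libraries
dominated by annotated small-RNA genes with an optional planted
21–23-nt break-derived species; DRIP fragment libraries (300–1000 nt)
with planted fold enrichment around cut sites and fragment ends that
can respect the 2-nt cut overhang; NB-distributed window count
matrices; qPCR CT replicates derived from a known resected fraction;
and a gene table standing in for nascent-transcription TPM
quantification. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .driptools import Fragment
from .matching import CutGene
from .quant import QpcrSample, delta_ct_for_fraction
from .sites import ASISI_MOTIF, GenomicSite, site_at
from .smallrna import (CLASS_HIERARCHY, DEFAULT_ADAPTER, CountMatrix,
                       SmallRead)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: canonical repair-class proportions of the annotated cut-site list
CLASS_PROPORTIONS = {"HR": 25, "NHEJ": 25, "unspecified": 49}

#: (number of intervals, interval length) per annotated small-RNA class
DEFAULT_ANNOTATION_PLAN = {
    "miRNA": (30, 80),
    "tRNA": (20, 75),
    "snRNA": (10, 150),
    "snoRNA": (10, 120),
    "scRNA": (5, 300),
    "YRNA": (5, 100),
    "sRNA": (5, 200),
}

#: read mixture of a small-RNA library: annotated classes dominate
DEFAULT_CLASS_MIXTURE = {
    "miRNA": 0.60, "tRNA": 0.15, "snRNA": 0.08, "snoRNA": 0.07,
    "scRNA": 0.04, "YRNA": 0.03, "sRNA": 0.03,
}


@dataclass
class SimTruth:
    """Ground truth of a simulated study, serialisable to YAML."""

    master_seed: int
    motif: str
    chrom_lengths: dict[str, int]
    sites: list[GenomicSite]
    annotations: dict[str, list[tuple[str, int, int]]] = field(
        default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def cut_sites(self) -> list[GenomicSite]:
        return [s for s in self.sites if s.repair_class != "uncut"]

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "motif": self.motif,
            "chrom_lengths": dict(self.chrom_lengths),
            "sites": [
                {"chrom": s.chrom, "motif_start": s.motif_start,
                 "repair_class": s.repair_class, "site_id": s.site_id}
                for s in self.sites
            ],
            "annotations": {
                cls: [list(iv) for iv in ivs]
                for cls, ivs in self.annotations.items()
            },
            "params": self.params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            master_seed=d["master_seed"],
            motif=d["motif"],
            chrom_lengths=dict(d["chrom_lengths"]),
            sites=[site_at(s["chrom"], s["motif_start"],
                           repair_class=s["repair_class"],
                           site_id=s.get("site_id"))
                   for s in d["sites"]],
            annotations={cls: [tuple(iv) for iv in ivs]
                         for cls, ivs in d.get("annotations", {}).items()},
            params=dict(d.get("params", {})),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


class PlacementError(RuntimeError):
    """Motif placement was infeasible under the separation constraints."""


def _find_all(hay: np.ndarray, needle: np.ndarray) -> np.ndarray:
    """All (overlapping) occurrence starts of needle in a uint8 array."""
    if len(hay) < len(needle):
        return np.array([], dtype=int)
    hits = hay[: len(hay) - len(needle) + 1] == needle[0]
    for k in range(1, len(needle)):
        hits &= hay[k: len(hay) - len(needle) + 1 + k] == needle[k]
    return np.flatnonzero(hits)


def simulate_genome(
    n_chrom: int = 3,
    chrom_length: int = 1_000_000,
    n_motifs: int = 40,
    n_cut: int = 12,
    class_fractions: Mapping[str, int] = CLASS_PROPORTIONS,
    seed: int = 0,
    motif: str = ASISI_MOTIF,
    min_separation: int = 25_000,
    margin: int = 10_000,
    max_retries: int = 50,
) -> tuple[dict[str, str], SimTruth]:
    """Random genome in which the motif occurs ONLY at planted positions.

    Spontaneous motif occurrences in the random background are erased by
    rejected resampling; ``n_motifs`` copies are then planted at
    positions at least ``min_separation`` apart (so site windows of
    different repair classes do not bleed into each other) and
    ``margin`` from chromosome ends. ``n_cut`` of them are labelled by
    repair class in ``class_fractions`` proportions (largest-remainder
    rounding); the rest are ``uncut``.
    """
    if n_cut > n_motifs:
        raise ValueError("n_cut must be <= n_motifs")
    rng = np.random.default_rng(seed)
    motif_arr = np.frombuffer(motif.encode(), dtype=np.uint8)
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    arrays = {c: _BASES[rng.integers(0, 4, size=chrom_length)]
              for c in chrom_names}

    # plant motifs: counts per chromosome ~ length; positions drawn as
    # sorted uniforms plus fixed spacing (exact uniform sampling under
    # the minimum-separation constraint)
    lengths = np.array([chrom_length] * n_chrom, dtype=float)
    placed: dict[str, list[int]] = {}
    for _ in range(max_retries):
        counts = rng.multinomial(n_motifs, lengths / lengths.sum())
        usable = [chrom_length - 2 * margin - 8
                  - max(k - 1, 0) * min_separation for k in counts]
        if all(u >= 0 for u in usable):
            placed = {}
            for c, k, u in zip(chrom_names, counts, usable):
                base = np.sort(rng.random(k)) * u + margin
                placed[c] = [int(b + i * min_separation)
                             for i, b in enumerate(base)]
            break
    else:
        raise PlacementError(
            "could not place motifs under the separation constraint"
        )
    for c, positions in placed.items():
        for pos in positions:
            arrays[c][pos: pos + 8] = motif_arr

    # erase every occurrence that is not a planted one
    for c in chrom_names:
        planted = set(placed[c])
        protected = np.zeros(chrom_length, dtype=bool)
        for pos in planted:
            protected[pos: pos + 8] = True
        for _ in range(max_retries):
            extras = [p for p in _find_all(arrays[c], motif_arr)
                      if p not in planted]
            if not extras:
                break
            for p in extras:
                span = np.arange(p, min(p + 8, chrom_length))
                free = span[~protected[span]]
                arrays[c][free] = _BASES[rng.integers(0, 4, size=free.size)]
        else:
            raise PlacementError("could not scrub spontaneous motifs")

    # repair classes: cut subset in largest-remainder proportions
    all_positions = [(c, p) for c in chrom_names for p in sorted(placed[c])]
    order = rng.permutation(len(all_positions))
    cut_idx = sorted(order[:n_cut])
    fracs = {k: v for k, v in class_fractions.items()}
    total = sum(fracs.values())
    quotas = {k: n_cut * v / total for k, v in fracs.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    leftover = n_cut - sum(counts.values())
    for k in sorted(quotas, key=lambda k: quotas[k] - counts[k],
                    reverse=True)[:leftover]:
        counts[k] += 1
    labels = [k for k in ("HR", "NHEJ", "unspecified")
              for _ in range(counts.get(k, 0))]
    rng.shuffle(labels)

    sites: list[GenomicSite] = []
    label_iter = iter(labels)
    cut_set = set(cut_idx)
    for i, (c, p) in enumerate(all_positions):
        cls = next(label_iter) if i in cut_set else "uncut"
        sites.append(site_at(c, p, repair_class=cls, site_id=f"site_{i}"))

    genome = {c: arrays[c].tobytes().decode() for c in chrom_names}
    annotations = _simulate_annotations(
        rng, {c: chrom_length for c in chrom_names}, sites)
    truth = SimTruth(
        master_seed=seed,
        motif=motif,
        chrom_lengths={c: chrom_length for c in chrom_names},
        sites=sites,
        annotations=annotations,
        params={"n_motifs": n_motifs, "n_cut": n_cut,
                "min_separation": min_separation},
    )
    return genome, truth


def _simulate_annotations(
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    sites: Sequence[GenomicSite],
    plan: Mapping[str, tuple[int, int]] = DEFAULT_ANNOTATION_PLAN,
    motif_clearance: int = 1000,
) -> dict[str, list[tuple[str, int, int]]]:
    """Annotated small-RNA gene intervals, clear of every motif window.

    Keeping annotations ``motif_clearance`` away from motif anchors
    guarantees that break-derived reads planted near cut sites stay in
    the residual class.
    """
    chroms = list(chrom_lengths)
    anchors = {c: np.array(sorted(s.cut_anchor for s in sites
                                  if s.chrom == c)) for c in chroms}
    out: dict[str, list[tuple[str, int, int]]] = {}
    for cls, (count, length) in plan.items():
        ivs: list[tuple[str, int, int]] = []
        while len(ivs) < count:
            c = chroms[rng.integers(len(chroms))]
            start = int(rng.integers(0, chrom_lengths[c] - length))
            near = anchors[c]
            if near.size:
                d = np.min(np.abs(near - (start + length / 2)))
                if d < motif_clearance + length:
                    continue
            ivs.append((c, start, start + length))
        out[cls] = ivs
    return out


@dataclass
class SmallRnaLibrary:
    """One simulated small-RNA sample: truth alignments plus raw FASTQ."""

    reads: list[SmallRead]       # truth placements (classes unassigned)
    sources: list[str]           # truth origin: class name|background|planted
    fastq: list[tuple[str, str, str]]  # (name, sequence, quality)


_COMPLEMENT_TABLE = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT_TABLE)[::-1]


def simulate_smallrna_library(
    truth: SimTruth,
    genome: Mapping[str, str],
    n_reads: int = 20_000,
    planted_dsb_fold: float = 1.0,
    planted_span: int = 500,
    adapter: str = DEFAULT_ADAPTER,
    seed: int = 0,
    read_length: int = 75,
    annotated_fraction: float = 0.7,
    class_mixture: Mapping[str, float] = DEFAULT_CLASS_MIXTURE,
) -> SmallRnaLibrary:
    """Simulate one small-RNA library.

    ``n_reads`` split into annotated small-RNA gene reads
    (``annotated_fraction``, apportioned by ``class_mixture``) and a
    uniform residual background. With ``planted_dsb_fold > 1`` an extra
    21–23-nt species is planted within ``+/- planted_span`` of each cut
    anchor so that the local residual read density there is
    ``planted_dsb_fold`` times background. Raw FASTQ reads are built as
    4 random nt + insert + 4 random nt + adapter, truncated to
    ``read_length``.
    """
    rng = np.random.default_rng(seed)
    chroms = list(truth.chrom_lengths)
    clens = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
    total_len = clens.sum()

    n_annotated = int(round(annotated_fraction * n_reads))
    n_background = n_reads - n_annotated
    reads: list[SmallRead] = []
    sources: list[str] = []

    mix_classes = [c for c in CLASS_HIERARCHY if c in class_mixture]
    weights = np.array([class_mixture[c] for c in mix_classes], dtype=float)
    weights /= weights.sum()
    per_class = rng.multinomial(n_annotated, weights)
    for cls, n_cls in zip(mix_classes, per_class):
        ivs = truth.annotations.get(cls, [])
        if not ivs:
            continue
        for _ in range(n_cls):
            chrom, s0, s1 = ivs[rng.integers(len(ivs))]
            length = (int(rng.integers(21, 24)) if cls == "miRNA"
                      else int(rng.integers(19, 27)))
            length = min(length, s1 - s0)
            start = int(rng.integers(s0, s1 - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(SmallRead(chrom, start, start + length, strand))
            sources.append(cls)

    for _ in range(n_background):
        ci = int(rng.choice(len(chroms), p=clens / total_len))
        chrom = chroms[ci]
        length = int(rng.integers(18, 31))
        start = int(rng.integers(0, truth.chrom_lengths[chrom] - length))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(SmallRead(chrom, start, start + length, strand))
        sources.append("background")

    cut = truth.cut_sites
    if planted_dsb_fold > 1.0 and cut:
        density = n_background / total_len
        lam = (planted_dsb_fold - 1.0) * density * 2 * planted_span
        for site in cut:
            n_extra = int(rng.poisson(lam))
            for _ in range(n_extra):
                length = int(rng.integers(21, 24))
                lo = site.cut_anchor - planted_span
                hi = site.cut_anchor + planted_span - length
                start = int(rng.integers(lo, hi + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                reads.append(SmallRead(site.chrom, start, start + length,
                                       strand))
                sources.append("planted")

    fastq: list[tuple[str, str, str]] = []
    for i, read in enumerate(reads):
        insert = genome[read.chrom][read.start: read.end].upper()
        if read.strand == "-":
            insert = _revcomp(insert)
        flank = _BASES[rng.integers(0, 4, size=8)].tobytes().decode()
        raw = (flank[:4] + insert + flank[4:] + adapter)[:read_length]
        fastq.append((f"read_{i}", raw, "I" * len(raw)))
    return SmallRnaLibrary(reads=reads, sources=sources, fastq=fastq)


def write_fastq(records: Sequence[tuple[str, str, str]],
                path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_fasta(genome: Mapping[str, str], path: str | Path,
                width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def simulate_region_counts(
    n_sites: int = 12,
    mu: float = 50.0,
    alpha: float = 0.05,
    n_control: int = 2,
    n_damage: int = 8,
    planted_site: int | None = None,
    planted_fold: float = 1.0,
    seed: int = 0,
) -> tuple[CountMatrix, list[str], list[str]]:
    """Negative-binomial window counts for the differential test.

    Mirrors the sequencing design — replicate libraries at the
    undamaged time point versus pooled damage time points — at the
    count level. ``planted_site`` (if given) has its damage-group mean
    multiplied by ``planted_fold``.
    """
    rng = np.random.default_rng(seed)
    control = [f"t0_r{j + 1}" for j in range(n_control)]
    damage = [f"damage_r{j + 1}" for j in range(n_damage)]
    mean = np.full((n_sites, n_control + n_damage), float(mu))
    if planted_site is not None:
        mean[planted_site, n_control:] *= planted_fold
    n_param = 1.0 / alpha
    p_param = n_param / (n_param + mean)
    counts = rng.negative_binomial(n_param, p_param)
    df = pd.DataFrame(counts, index=[f"site_{i}" for i in range(n_sites)],
                      columns=control + damage)
    lib = df.sum(axis=0) * 20 + 1000  # windows hold a minority of reads
    return CountMatrix(counts=df, library_sizes=lib), control, damage


def simulate_drip_library(
    truth: SimTruth,
    n_fragments: int = 10_000,
    enrichment_fold: float | Mapping[str, float] = 4.0,
    span: int = 1000,
    adherence: float = 0.0,
    seed: int = 0,
    fragment_length: tuple[int, int] = (300, 1000),
) -> dict[str, list[Fragment]]:
    """Simulate DRIP fragment libraries for both conditions.

    Undamaged fragments are uniform over the genome with lengths
    ~ Uniform(300, 1000). In the damaged condition, fragment coverage is
    multiplied by the class's enrichment fold within ``+/- span`` of
    each cut anchor: extra fragments are drawn with the same conditional
    distribution that background fragments overlapping the span have
    (length-biased length, start uniform over the overlap range), so the
    planted coverage ratio is uniform across the span rather than
    peaked at its centre. Mirroring the in-vitro digestion of the
    damaged template, a fragment overlapping a cut is, with probability
    ``adherence``, truncated at the cut so that it never covers the 2-nt
    overhang.
    """
    if isinstance(enrichment_fold, Mapping):
        folds = dict(enrichment_fold)
    else:
        folds = {c: float(enrichment_fold)
                 for c in ("HR", "NHEJ", "unspecified")}
    if any(f < 1 for f in folds.values()):
        raise ValueError("enrichment_fold must be >= 1")
    if span <= 0:
        raise ValueError("span must be positive")
    rng = np.random.default_rng(seed)
    chroms = list(truth.chrom_lengths)
    clens = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
    total_len = clens.sum()
    lo, hi = fragment_length

    mean_len = (lo + hi) / 2.0
    windows = [(s, folds.get(s.repair_class, 1.0)) for s in truth.cut_sites]
    windows = [(s, f) for s, f in windows if f > 1.0]
    # expected number of background fragments overlapping a span window
    # scales with (2*span + L); extras in that proportion give exactly
    # fold-times coverage inside the span
    wweights = np.array([(f - 1.0) * (2 * span + mean_len)
                         for _, f in windows])
    extra = wweights.sum()
    # length-biased fragment-length distribution for overlap-conditioned
    # draws
    len_values = np.arange(lo, hi + 1)
    len_p = (2 * span + len_values - 1).astype(float)
    len_p /= len_p.sum()

    overhangs = {c: np.array(sorted(s.overhang[0] for s in truth.cut_sites
                                    if s.chrom == c)) for c in chroms}

    anchor_arr = np.array([s.cut_anchor for s, _ in windows], dtype=np.int64)
    wchrom_arr = np.array([chroms.index(s.chrom) for s, _ in windows])
    clen_arr = np.array([truth.chrom_lengths[c] for c in chroms],
                        dtype=np.int64)

    out: dict[str, list[Fragment]] = {}
    for condition in ("undamaged", "damaged"):
        enriched = condition == "damaged" and extra > 0
        n = n_fragments
        n_extra = int(rng.binomial(n, extra / (total_len + extra))) \
            if enriched else 0
        n_bg = n - n_extra

        ci = rng.choice(len(chroms), size=n_bg, p=clens / total_len)
        lengths_bg = rng.integers(lo, hi + 1, size=n_bg)
        starts_bg = (rng.random(n_bg)
                     * (clen_arr[ci] - lengths_bg)).astype(np.int64)
        chrom_idx = ci
        starts, lengths = starts_bg, lengths_bg

        if n_extra:
            widx = rng.choice(len(windows), size=n_extra,
                              p=wweights / wweights.sum())
            lengths_en = rng.choice(len_values, size=n_extra, p=len_p)
            # any start whose fragment overlaps [anchor-span, anchor+span)
            lo_start = anchor_arr[widx] - span - lengths_en + 1
            starts_en = lo_start + (rng.random(n_extra)
                                    * (2 * span + lengths_en - 1)
                                    ).astype(np.int64)
            cl = clen_arr[wchrom_arr[widx]]
            starts_en = np.clip(starts_en, 0, cl - lengths_en)
            chrom_idx = np.concatenate([chrom_idx, wchrom_arr[widx]])
            starts = np.concatenate([starts, starts_en])
            lengths = np.concatenate([lengths, lengths_en])
        ends = starts + lengths

        if condition == "damaged" and adherence > 0:
            for k in np.flatnonzero(rng.random(n) < adherence):
                ohs = overhangs[chroms[chrom_idx[k]]]
                if not ohs.size:
                    continue
                hit = ohs[(ohs + 2 > starts[k]) & (ohs < ends[k])]
                if not hit.size:
                    continue
                o0 = int(hit[0])  # truncate at the first overlapped cut
                left_len = max(o0 - starts[k], 0)
                right_len = max(ends[k] - (o0 + 2), 0)
                total = left_len + right_len
                if total == 0:
                    starts[k], ends[k] = 0, 0  # degenerate; drop below
                    continue
                keep_left = rng.random() < left_len / total
                if keep_left and left_len > 0 or right_len == 0:
                    ends[k] = o0
                else:
                    starts[k] = o0 + 2

        frags = [
            Fragment(chrom=chroms[c], start=int(s), end=int(e),
                     condition=condition)
            for c, s, e in zip(chrom_idx, starts, ends)
            if e > s
        ]
        out[condition] = frags
    return out


def emit_fragments_sam(
    fragments: Sequence[Fragment],
    chrom_lengths: Mapping[str, int],
    path: str | Path,
    read_length: int = 75,
) -> None:
    """Write each fragment as a proper mate pair of ``read_length``-nt
    alignments (no aligner in the loop), suitable for
    :func:`dsbrna.driptools.fragments_from_sam` round-trips."""
    chroms = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for i, f in enumerate(fragments):
            m1 = (f.start, min(f.start + read_length, f.end))
            m2 = (max(f.end - read_length, f.start), f.end)
            for which, (s, e) in enumerate((m1, m2)):
                a = pysam.AlignedSegment()
                a.query_name = f"frag_{i}"
                a.reference_id = tid[f.chrom]
                a.reference_start = s
                a.cigar = [(0, e - s)]
                a.flag = 0x1 | 0x2 | (0x40 if which == 0 else 0x80) \
                    | (0x20 if which == 0 else 0x10)
                a.next_reference_id = tid[f.chrom]
                a.next_reference_start = m2[0] if which == 0 else m1[0]
                a.template_length = (f.end - f.start) * (1 if which == 0
                                                         else -1)
                a.mapping_quality = 60
                fh.write(a)


def simulate_qpcr_resection(
    f: float,
    sigma_ct: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
    base_ct: float = 22.0,
) -> tuple[QpcrSample, QpcrSample]:
    """CT replicates for a known resected fraction ``f`` (percent).

    ΔCT is set by inverting the %ssDNA formula
    (``dCT = 1 + log2(100/f - 0.5)``); undigested CTs are
    Normal(``base_ct``, σ) and digested CTs add ΔCT plus independent
    Normal(0, σ) noise. With σ = 0 the round trip through
    :func:`dsbrna.quant.percent_ssdna` is exact.
    """
    if f <= 0:
        raise ValueError("true fraction must be positive")
    dct = delta_ct_for_fraction(f)
    rng = np.random.default_rng(seed)
    undig = base_ct + rng.normal(0.0, sigma_ct, size=n_reps)
    dig = undig.mean() + dct + rng.normal(0.0, sigma_ct, size=n_reps)
    return (
        QpcrSample(target="resection", condition=f"f={f}", role="digested",
                   ct_values=tuple(float(x) for x in dig)),
        QpcrSample(target="resection", condition=f"f={f}", role="undigested",
                   ct_values=tuple(float(x) for x in undig)),
    )


def simulate_gene_table(
    truth: SimTruth,
    n_genes: int = 1000,
    tpm_meanlog: float = 1.0,
    tpm_sdlog: float = 1.2,
    length_meanlog: float = 9.5,
    length_sdlog: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[CutGene]]:
    """Gene table with TPM/length log-normal marginals plus host genes.

    Every cut site is assigned a host gene that contains its cut anchor;
    the returned :class:`CutGene` records carry the strand-aware TSS
    distance the matching stage anchors controls at.
    """
    rng = np.random.default_rng(seed)
    chroms = list(truth.chrom_lengths)
    clens = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
    rows = []
    for i in range(n_genes):
        ci = int(rng.choice(len(chroms), p=clens / clens.sum()))
        chrom = chroms[ci]
        clen = truth.chrom_lengths[chrom]
        length = int(np.clip(rng.lognormal(length_meanlog, length_sdlog),
                             500, clen // 2))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss = int(rng.integers(0, clen - length))
        else:
            tss = int(rng.integers(length, clen))
        rows.append({"gene_id": f"gene_{i}", "chrom": chrom,
                     "strand": strand, "tss": tss, "gene_length": length,
                     "tpm": float(rng.lognormal(tpm_meanlog, tpm_sdlog))})
    cut_genes: list[CutGene] = []
    for s in truth.cut_sites:
        clen = truth.chrom_lengths[s.chrom]
        length = int(np.clip(rng.lognormal(length_meanlog, length_sdlog),
                             2000, clen // 2))
        strand = "+" if rng.random() < 0.5 else "-"
        d_max = length - 200
        d = int(rng.integers(200, max(d_max, 201)))
        if strand == "+":
            tss = s.cut_anchor - d
            if tss < 0 or tss + length > clen:
                tss = max(0, min(tss, clen - length))
                d = s.cut_anchor - tss
        else:
            tss = s.cut_anchor + d
            if tss > clen or tss - length < 0:
                tss = min(clen - 1, max(tss, length))
                d = tss - s.cut_anchor
        gid = f"cutgene_{s.site_id}"
        rows.append({"gene_id": gid, "chrom": s.chrom, "strand": strand,
                     "tss": tss, "gene_length": length,
                     "tpm": float(rng.lognormal(tpm_meanlog, tpm_sdlog))})
        cut_genes.append(CutGene(site_id=s.site_id or s.name, gene_id=gid,
                                 tss_distance=d))
    return pd.DataFrame(rows), cut_genes


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
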