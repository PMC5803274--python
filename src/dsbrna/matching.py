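"""Transcription-matched control-site selection.

Break-proximal signal must be compared against undamaged loci of
similar transcriptional activity: for every cut site hosted in a gene,
a control gene with a similar nascent-transcription TPM and a similar
length is drawn at random, and the control anchor is placed at the same
distance from the control gene's TSS as the cut site sits from its host
gene's TSS (strand-aware). Control genes never contain a recognition
motif within the analysis window, so — like an empty-vector control —
they can never have been cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sites import GenomicSite

logger = logging.getLogger(__name__)

#: base half-width of the tolerance box in log10 units, for both
#: log10(TPM + PSEUDO_TPM) and log10(length)
BASE_TOLERANCE = 0.25
#: pseudocount added to TPM before log10 (handles zero-TPM genes)
PSEUDO_TPM = 0.01

GENE_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "tss", "gene_length",
                      "tpm"]


@dataclass(frozen=True)
class TPMRecord:
    """One gene of the nascent-transcription quantification table."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_length: int
    tpm: float

    def __post_init__(self) -> None:
        if self.tpm < 0:
            raise ValueError("tpm must be >= 0")
        if self.gene_length <= 0:
            raise ValueError("gene_length must be positive")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class CutGene:
    """A cut site together with its host gene and TSS distance.

    ``tss_distance`` is measured along the host gene's strand
    (downstream positive).
    """

    site_id: str
    gene_id: str
    tss_distance: int


@dataclass(frozen=True)
class MatchedSite:
    """A control anchor matched to one cut site."""

    gene_id: str
    chrom: str
    anchor: int
    matched_to: str
    tolerance_used: float


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV gene table (gene_id, chrom, strand, tss, gene_length, tpm)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    return df


def _anchor_for(tss: int, strand: str, tss_distance: int) -> int:
    return tss + tss_distance if strand == "+" else tss - tss_distance


def match_control_sites(
    cut_genes: Sequence[CutGene],
    gene_table: pd.DataFrame,
    *,
    seed: int,
    half_width: int = 5000,
    base_tolerance: float = BASE_TOLERANCE,
    motif_sites: Sequence[GenomicSite] = (),
    chrom_lengths: Mapping[str, int] | None = None,
    with_replacement: bool = False,
) -> list[MatchedSite]:
    """Draw one transcription-matched control gene per cut site.

    Candidates are genes (excluding every cut-hosting gene) within
    ``+/- base_tolerance`` of the cut gene in both
    ``log10(TPM + 0.01)`` and ``log10(length)``; one is drawn uniformly
    at random. If no candidate qualifies — or all qualifying candidates
    are rejected because the anchor window leaves the chromosome or
    contains a recognition motif — the tolerance doubles (logged) until
    a match is found. Default is matching without replacement across
    sites.
    """
    if gene_table.empty:
        raise ValueError("empty gene table")
    genes = gene_table.set_index("gene_id")
    cut_ids = {cg.gene_id for cg in cut_genes}
    rng = np.random.default_rng(seed)

    log_tpm = np.log10(genes["tpm"].to_numpy(dtype=float) + PSEUDO_TPM)
    log_len = np.log10(genes["gene_length"].to_numpy(dtype=float))
    gene_ids = genes.index.to_numpy()
    pool_mask = ~np.isin(gene_ids, list(cut_ids))

    # motif anchors per chromosome, for the cut-free window check
    motif_by_chrom: dict[str, np.ndarray] = {}
    for s in motif_sites:
        motif_by_chrom.setdefault(s.chrom, [])
    for s in motif_sites:
        motif_by_chrom[s.chrom].append(s.cut_anchor)
    motif_by_chrom = {c: np.sort(np.array(v))
                      for c, v in motif_by_chrom.items()}

    used: set[str] = set()
    matched: list[MatchedSite] = []
    for cg in cut_genes:
        if cg.gene_id not in genes.index:
            logger.warning("cut site %s: host gene %s not in table; skipped",
                           cg.site_id, cg.gene_id)
            continue
        row = genes.loc[cg.gene_id]
        target_tpm = np.log10(float(row["tpm"]) + PSEUDO_TPM)
        target_len = np.log10(float(row["gene_length"]))
        tol = base_tolerance
        pick: MatchedSite | None = None
        while pick is None:
            ok = (
                pool_mask
                & (np.abs(log_tpm - target_tpm) <= tol)
                & (np.abs(log_len - target_len) <= tol)
            )
            if not with_replacement and used:
                ok &= ~np.isin(gene_ids, list(used))
            candidates = list(np.flatnonzero(ok))
            if not candidates:
                tol *= 2
                logger.info("cut site %s: no candidate at tolerance; "
                            "doubled to %.3g", cg.site_id, tol)
                if tol > 1e6:
                    raise RuntimeError(
                        f"cut site {cg.site_id}: no control gene found"
                    )
                continue
            rng.shuffle(candidates)
            for idx in candidates:
                gid = str(gene_ids[idx])
                g = genes.loc[gid]
                anchor = _anchor_for(int(g["tss"]), str(g["strand"]),
                                     cg.tss_distance)
                chrom = str(g["chrom"])
                if chrom_lengths is not None:
                    clen = chrom_lengths.get(chrom)
                    if clen is None or not (0 <= anchor < clen):
                        continue  # clipped anchor: reject candidate
                hits = motif_by_chrom.get(chrom)
                if hits is not None and hits.size:
                    lo = np.searchsorted(hits, anchor - half_width, "left")
                    hi = np.searchsorted(hits, anchor + half_width, "right")
                    if hi > lo:
                        continue  # motif inside window: reject
                pick = MatchedSite(gene_id=gid, chrom=chrom, anchor=anchor,
                                   matched_to=cg.site_id,
                                   tolerance_used=tol)
                break
            else:
                tol *= 2
                logger.info("cut site %s: all candidates rejected; "
                            "tolerance doubled to %.3g", cg.site_id, tol)
                if tol > 1e6:
                    raise RuntimeError(
                        f"cut site {cg.site_id}: no control gene found"
                    )
        if not with_replacement:
            used.add(pick.gene_id)
        matched.append(pick)
    return matched


def write_matched_bed(matched: Sequence[MatchedSite],
                      path: str | Path) -> None:
    """Write matched anchors as BED (1-bp intervals, name=matched cut site)."""
    with open(path, "w") as fh:
        for m in matched:
            fh.write(f"{m.chrom}\t{m.anchor}\t{m.anchor + 1}\t"
                     f"{m.matched_to}\t0\t+\n")
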