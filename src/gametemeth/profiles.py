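"""Genome-scale methylation profiles.

CpG density is the number of CpG dinucleotides in a 200-nt window centred
on the queried site, divided by the window length (1 CpG / 200 nt = 0.005).
Density-stratified methylation curves pool aligned C/T counts per density
bin; fixed-width window tracks and methylation-level histograms summarise
the per-site calls genome-wide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import Genome, merged_intervals

DENSITY_WINDOW = 200
ELEMENT_MASKS = ("whole_genome", "LINE", "SINE", "LTR", "DNA")


def cpg_density_track(genome: Genome, chrom: str,
                      window: int = DENSITY_WINDOW) -> np.ndarray:
    """Per-position CpG density (float32) for a whole contig.

    Windows truncated at contig ends are renormalised to their actual
    length.
    """
    e = genome.enc(chrom)
    n = len(e)
    ind = np.zeros(n + 1, dtype=np.int64)
    starts = genome.cpg_starts(chrom)
    ind[starts + 1] = 1
    cum = np.cumsum(ind)
    half = window // 2
    pos = np.arange(n)
    lo = np.maximum(pos - half, 0)
    hi = np.minimum(pos + half, n)
    # dinucleotide must lie fully inside [lo, hi)
    count = cum[np.maximum(hi - 1, lo)] - cum[lo]
    return (count / (hi - lo)).astype(np.float32)


def cpg_density(genome: Genome, chrom: str, pos: int,
                window: int = DENSITY_WINDOW) -> float:
    """Density of the 200-nt window centred on (chrom, pos)."""
    n = len(genome.sequences[chrom])
    half = window // 2
    lo, hi = max(pos - half, 0), min(pos + half, n)
    starts = genome.cpg_starts(chrom)
    count = int(np.searchsorted(starts, hi - 1) - np.searchsorted(starts, lo))
    return count / (hi - lo)


def density_methylation_curve(calls, genome: Genome | None = None,
                              element_mask: str = "whole_genome",
                              bin_width: float = 0.005, d_max: float = 0.25,
                              min_genomic_cpgs: int = 100) -> pd.DataFrame:
    """Pooled CpG methylation as a function of local CpG density.

    One row per density bin: d_lo, d_mid, c, t, n_genomic_cpgs, percent,
    excluded. Bins containing fewer than ``min_genomic_cpgs`` genomic CpGs
    are flagged excluded (percent = NaN). ``element_mask`` restricts sites
    to one transposable-element family's intervals.
    """
    genome = genome or calls.genome
    if element_mask not in ELEMENT_MASKS:
        raise ValueError(f"element_mask must be one of {ELEMENT_MASKS}")
    edges = np.arange(bin_width, d_max + bin_width, bin_width)
    nb = len(edges)
    cagg = np.zeros(nb, np.int64)
    tagg = np.zeros(nb, np.int64)
    ngen = np.zeros(nb, np.int64)
    mask_iv = None
    if element_mask != "whole_genome":
        mask_iv = merged_intervals(
            genome.repeats[genome.repeats.family == element_mask])
        if not mask_iv:
            return _curve_frame(edges, cagg, tagg, ngen, min_genomic_cpgs,
                                bin_width)
    for chrom in genome.analysis_chroms:
        p, c, t = calls.cpg_site_counts(chrom)
        if len(p) == 0:
            continue
        if mask_iv is not None:
            if chrom not in mask_iv:
                continue
            ms, me = mask_iv[chrom]
            i = np.searchsorted(me, p, side="right")
            sel = (i < len(ms)) & (ms[np.minimum(i, len(ms) - 1)] <= p)
            p, c, t = p[sel], c[sel], t[sel]
            if len(p) == 0:
                continue
        d = cpg_density_track(genome, chrom)[p]
        b = np.minimum((np.maximum(d, 1e-9) / bin_width - 1e-9).astype(int),
                       nb - 1)
        np.add.at(ngen, b, 1)
        covered = (c + t) > 0
        np.add.at(cagg, b[covered], c[covered])
        np.add.at(tagg, b[covered], t[covered])
    return _curve_frame(edges, cagg, tagg, ngen, min_genomic_cpgs, bin_width)


def _curve_frame(edges, cagg, tagg, ngen, min_genomic, bin_width):
    d_lo = edges - bin_width
    depth = cagg + tagg
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(depth > 0, 100.0 * cagg / np.maximum(depth, 1),
                           np.nan)
    excluded = ngen < min_genomic
    percent = np.where(excluded, np.nan, percent)
    return pd.DataFrame({
        "d_lo": d_lo, "d_mid": d_lo + bin_width / 2, "c": cagg, "t": tagg,
        "n_genomic_cpgs": ngen, "percent": percent, "excluded": excluded})


def window_methylation_track(calls, genome: Genome | None = None,
                             width: int = 10_000) -> pd.DataFrame:
    """Pooled CpG percent in non-overlapping windows tiling each analysis
    chromosome (chrM, chrY and the spike-in are excluded). Windows with no
    calls carry percent = NaN."""
    genome = genome or calls.genome
    if width < 1000:
        raise ValueError("window width below 1 kb is not supported")
    rows = []
    for chrom in genome.analysis_chroms:
        n = len(genome.sequences[chrom])
        p, c, t = calls.cpg_site_counts(chrom)
        nb = -(-n // width)
        cagg = np.zeros(nb, np.int64)
        tagg = np.zeros(nb, np.int64)
        if len(p):
            b = p // width
            np.add.at(cagg, b, c)
            np.add.at(tagg, b, t)
        for i in range(nb):
            depth = cagg[i] + tagg[i]
            rows.append((chrom, i * width, min((i + 1) * width, n),
                         100.0 * cagg[i] / depth if depth else np.nan))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "percent"])


def methylation_level_histogram(calls, bin_width: int = 10,
                                min_depth: int = 1, chroms=None) -> pd.DataFrame:
    """Fractions of informative CpG cytosines per percent-methylation bin.

    Bins are [0,10), [10,20), ..., [90,100] — the top bin is closed, so a
    site at exactly 90% falls in the last (">=90%") bin.
    """
    genome = calls.genome
    chroms = genome.analysis_chroms if chroms is None else chroms
    nb = 100 // bin_width
    counts = np.zeros(nb, np.int64)
    for chrom in chroms:
        _, _, c, t = calls.cpg_cytosine_counts(chrom)
        depth = c + t
        sel = depth >= min_depth
        pct = 100.0 * c[sel] / depth[sel]
        b = np.minimum((pct // bin_width).astype(int), nb - 1)
        counts += np.bincount(b, minlength=nb)
    total = counts.sum()
    frac = counts / total if total else np.zeros(nb)
    return pd.DataFrame({
        "bin_lo": np.arange(nb) * bin_width,
        "bin_hi": np.arange(1, nb + 1) * bin_width,
        "count": counts, "fraction": frac})


def global_cpg_percent(calls, chroms=None) -> float:
    """Pooled CpG methylation percent over analysis chromosomes."""
    genome = calls.genome
    chroms = genome.analysis_chroms if chroms is None else chroms
    c = t = 0
    for chrom in chroms:
        _, cc, tt = calls.cpg_site_counts(chrom)
        c += int(cc.sum())
        t += int(tt.sum())
    if c + t == 0:
        raise ValueError("no CpG calls")
    return 100.0 * c / (c + t)


def plot_histogram(hist: pd.DataFrame, path) -> None:
    """Optional PNG rendering of a methylation-level histogram."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(hist.bin_lo, hist.fraction, width=hist.bin_hi - hist.bin_lo,
           align="edge", edgecolor="k")
    ax.set_xlabel("CpG methylation (%)")
    ax.set_ylabel("fraction of CpGs")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_density_curve(curves: dict[str, pd.DataFrame], path) -> None:
    """Optional PNG of density-vs-methylation curves, one line per sample."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3))
    for label, cur in curves.items():
        ok = ~cur.excluded
        ax.plot(cur.d_mid[ok], cur.percent[ok], marker="o", ms=2, label=label)
    ax.set_xlabel("CpG density (CpG/nt)")
    ax.set_ylabel("methylation (%)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
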