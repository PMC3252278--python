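"""Expression quantification and methylation-expression integration.

mRNA-seq tags are matched exactly (no mismatches) against spliced
transcript sequence after trimming the leading base; expression is RPKM =
1e9 * count / (exonic_length * library_size). Genes are ranked by RPKM and
split into five quintile groups (1 = most expressed) for metagene
methylation profiles around the TSS/TTS and rank-correlation tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .align import ExactIndex
from .genome import Genome

SIGNIFICANCE_P = 1e-9


@dataclass
class RegionSpec:
    """Strand-aware promoter / gene-body region definitions (bp)."""

    promoter_halfwidth: int = 500       # TSS +/- 500
    body1_from_tss: tuple[int, int] = (2000, 5000)
    body2_from_tts: int = 5000          # 0 to -5 kb from the TTS

    def interval(self, gene, which: str, chrom_len: int | None = None):
        """[start, end) of the named region for one gene; may be empty."""
        plus = gene.strand == "+"
        tss = gene.start if plus else gene.end - 1
        tts = gene.end - 1 if plus else gene.start
        if which == "promoter":
            s, e = tss - self.promoter_halfwidth, tss + self.promoter_halfwidth
        elif which == "gene_body_1":
            a, b = self.body1_from_tss
            if gene.end - gene.start <= a:
                return (0, 0)
            if plus:
                s, e = gene.start + a, min(gene.start + b, gene.end)
            else:
                s, e = max(gene.end - b, gene.start), gene.end - a
        elif which == "gene_body_2":
            w = self.body2_from_tts
            if plus:
                s, e = max(gene.end - w, gene.start), gene.end
            else:
                s, e = gene.start, min(gene.start + w, gene.end)
        else:
            raise ValueError(f"unknown region {which!r}")
        s = max(s, 0)
        if chrom_len is not None:
            e = min(e, chrom_len)
        return (s, e) if e > s else (0, 0)


@dataclass
class CorrelationResult:
    spearman_rho: float | None
    p_value: float | None
    n_genes: int
    significant: bool
    region: str = ""
    defined: bool = True


def compute_rpkm(tags, genome: Genome, trim_first: int = 1,
                 tag_length: int = 35) -> pd.DataFrame:
    """Count perfectly matching tags per gene and derive RPKM.

    ``tags``: iterable of (tag_id, sequence). Each tag is trimmed of its
    first ``trim_first`` nt, truncated to ``tag_length``, and matched
    exactly against every spliced transcript; tags matching more than one
    gene are discarded as ambiguous (counted in ``df.attrs``).
    """
    genes = genome.genes
    tx_seqs, gene_ids, lens = [], [], []
    for g in genes.itertuples():
        t = genome.spliced_transcript(g)
        if len(t) == 0:
            continue
        tx_seqs.append(t)
        gene_ids.append(g.gene_id)
        lens.append(len(t))
    joined = "N".join(tx_seqs)
    index = ExactIndex(joined)
    bounds = np.concatenate([[0], np.cumsum(np.asarray(lens[:-1]) + 1)]) \
        if len(lens) > 1 else np.array([0])
    ends = bounds + np.asarray(lens)

    counts = dict.fromkeys(gene_ids, 0)
    n_ambiguous = n_unmatched = 0
    for _tid, seq in tags:
        q = seq.upper()[trim_first:trim_first + tag_length]
        if len(q) < tag_length:
            n_unmatched += 1
            continue
        hits = index.find(q)
        owners = set()
        for gp in hits:
            i = int(np.searchsorted(bounds, gp, side="right")) - 1
            if gp + len(q) <= ends[i]:
                owners.add(gene_ids[i])
        if len(owners) == 1:
            counts[owners.pop()] += 1
        elif len(owners) > 1:
            n_ambiguous += 1
        else:
            n_unmatched += 1
    library = sum(counts.values())
    df = pd.DataFrame({"gene_id": gene_ids, "count": [counts[g] for g in
                                                      gene_ids],
                       "exonic_length": lens})
    df["library_size"] = library
    df["rpkm"] = (1e9 * df["count"] /
                  (df.exonic_length * max(library, 1)))
    df.attrs["n_ambiguous"] = n_ambiguous
    df.attrs["n_unmatched"] = n_unmatched
    return df


def assign_expression_groups(records: pd.DataFrame,
                             n_groups: int = 5) -> pd.DataFrame:
    """Rank genes by RPKM (descending) and assign quintile groups (1=top).

    Ties keep the stable input (gene_id) order; group sizes differ by at
    most one.
    """
    if len(records) < n_groups:
        raise ValueError(f"need at least {n_groups} genes to form groups")
    out = records.sort_values("rpkm", ascending=False,
                              kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    group = np.empty(len(out), dtype=int)
    for gi, chunk in enumerate(np.array_split(np.arange(len(out)), n_groups)):
        group[chunk] = gi + 1
    out["group"] = group
    return out


def metagene_methylation_profile(calls, genome: Genome | None,
                                 records: pd.DataFrame, anchor: str = "TSS",
                                 span: int = 5000, bin_width: int = 20
                                 ) -> pd.DataFrame:
    """Quintile-averaged methylation around the TSS or TTS.

    For each gene, +/- span around the anchor is divided into
    ``2*span/bin_width`` bins; each bin's value is the mean percent over its
    covered CpG cytosines, computed per gene and then averaged across the
    genes of each expression group (bins without coverage are skipped in
    the gene-level average). Offsets are transcriptional: positive =
    downstream, negative = upstream, for both strands.
    """
    if anchor not in ("TSS", "TTS"):
        raise ValueError("anchor must be TSS or TTS")
    genome = genome or calls.genome
    nb = 2 * span // bin_width
    groups = sorted(records.group.unique())
    sums = {g: np.zeros(nb) for g in groups}
    ngene = {g: np.zeros(nb, dtype=int) for g in groups}
    gene_rows = records.merge(genome.genes, on="gene_id", how="inner")
    cache = {}
    for g in gene_rows.itertuples():
        chrom = g.chrom
        if chrom not in cache:
            pos, minus, c, t = calls.cpg_cytosine_counts(chrom)
            order = np.argsort(pos, kind="stable")
            cache[chrom] = (pos[order], c[order], t[order])
        pos, c, t = cache[chrom]
        plus = g.strand == "+"
        if anchor == "TSS":
            a = g.start if plus else g.end - 1
        else:
            a = g.end - 1 if plus else g.start
        lo, hi = np.searchsorted(pos, (a - span, a + span))
        p, cc, tt = pos[lo:hi], c[lo:hi], t[lo:hi]
        depth = cc + tt
        sel = depth >= 1
        if not sel.any():
            continue
        p, cc, depth = p[sel], cc[sel], depth[sel]
        off = (p - a) if plus else (a - p)
        binidx = (off + span) // bin_width
        ok = (binidx >= 0) & (binidx < nb)
        binidx = binidx[ok].astype(int)
        pct = 100.0 * cc[ok] / depth[ok]
        ssum = np.bincount(binidx, weights=pct, minlength=nb)
        scnt = np.bincount(binidx, minlength=nb)
        covered = scnt > 0
        sums[g.group][covered] += ssum[covered] / scnt[covered]
        ngene[g.group][covered] += 1
    rows = []
    for grp in groups:
        with np.errstate(invalid="ignore"):
            mean = np.where(ngene[grp] > 0, sums[grp] /
                            np.maximum(ngene[grp], 1), np.nan)
        for i in range(nb):
            rows.append((anchor, grp, -span + i * bin_width + bin_width // 2,
                         mean[i], ngene[grp][i]))
    return pd.DataFrame(rows, columns=["anchor", "group", "bin_offset",
                                       "mean_percent", "n_genes"])


def regional_methylation_by_gene(calls, genome: Genome, region: str,
                                 spec: RegionSpec | None = None) -> pd.Series:
    """Pooled CpG percent of the named region for every gene (NaN when the
    region has no covered CpGs)."""
    spec = spec or RegionSpec()
    cache = {}
    vals = {}
    for g in genome.genes.itertuples():
        chrom = g.chrom
        if chrom not in cache:
            cache[chrom] = calls.cpg_site_counts(chrom)
        pos, c, t = cache[chrom]
        s, e = spec.interval(g, region, len(genome.sequences[chrom]))
        lo, hi = np.searchsorted(pos, (s, e))
        tot = int(c[lo:hi].sum() + t[lo:hi].sum())
        vals[g.gene_id] = 100.0 * c[lo:hi].sum() / tot if tot else np.nan
    return pd.Series(vals, name=region)


def expression_methylation_correlation(records: pd.DataFrame, calls,
                                       genome: Genome, region: str,
                                       spec: RegionSpec | None = None
                                       ) -> CorrelationResult:
    """Spearman rank correlation of expression vs regional methylation."""
    meth = regional_methylation_by_gene(calls, genome, region, spec)
    df = records.set_index("gene_id").join(meth.rename("meth"), how="inner")
    df = df.dropna(subset=["meth"])
    if len(df) < 10:
        raise ValueError("need >= 10 genes with informative regional "
                         "methylation")
    if df.rpkm.nunique() == 1 or df.meth.nunique() == 1:
        return CorrelationResult(None, None, len(df), False, region,
                                 defined=False)
    rho, p = stats.spearmanr(df.rpkm, df.meth)
    return CorrelationResult(float(rho), float(p), len(df),
                             bool(p < SIGNIFICANCE_P), region)


def rpkm_concordance(records_a: pd.DataFrame,
                     records_b: pd.DataFrame) -> float:
    """Squared Pearson correlation of RPKM over the shared gene universe."""
    merged = records_a[["gene_id", "rpkm"]].merge(
        records_b[["gene_id", "rpkm"]], on="gene_id",
        suffixes=("_a", "_b"))
    if len(merged) == 0:
        raise ValueError("disjoint gene sets")
    r, _ = stats.pearsonr(merged.rpkm_a, merged.rpkm_b)
    return float(r * r)
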