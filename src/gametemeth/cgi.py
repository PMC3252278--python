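"""CGI methylation, germline DMR calling and classification.

A germline differentially methylated region (gDMR) is a CGI with >=80%
mean methylation in one gamete and <=20% in the other (both boundaries
inclusive). gDMRs are further classified by genomic location (promoter or
first exon > last exon > other exon > intron > intergenic, in that
precedence), by the expression quintile of the host gene in the methylated
gamete, and by post-fertilization fate (demethylation-resistant means >=20%
methylation retained in blastocysts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome

LOCATIONS = ("promoter_or_first_exon", "last_exon", "other_exon", "intron",
             "intergenic")


@dataclass
class DmrParams:
    hi: float = 80.0
    lo: float = 20.0
    confirm_hi: float = 75.0
    confirm_lo: float = 25.0
    resist_min: float = 20.0
    highmeth_min: float = 80.0
    min_covered_cpgs: int = 3
    min_total_calls: int = 10
    promoter_upstream: int = 500

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("DmrParams requires lo < hi")
        if not self.confirm_lo < self.confirm_hi:
            raise ValueError("DmrParams requires confirm_lo < confirm_hi")


def cgi_methylation_table(sample_calls: dict, cgi_bed: pd.DataFrame,
                          genome: Genome | None = None,
                          params: DmrParams | None = None) -> pd.DataFrame:
    """Per-CGI pooled methylation percent for each sample.

    ``sample_calls`` maps sample name -> CallSet. Output columns:
    cgi_id, chrom, start, end, then per sample ``<name>`` (percent, NaN when
    non-informative) and ``<name>_informative``. A CGI is informative in a
    sample when it has >= ``min_covered_cpgs`` covered CpG dinucleotides and
    >= ``min_total_calls`` pooled calls.
    """
    p = params or DmrParams()
    first = next(iter(sample_calls.values()))
    genome = genome or first.genome
    out = cgi_bed[["cgi_id", "chrom", "start", "end"]].copy()
    # annotation sanity: every CGI must contain a reference CpG
    for r in cgi_bed.itertuples():
        starts = genome.cpg_starts(r.chrom)
        n_ref = int(np.searchsorted(starts, r.end) -
                    np.searchsorted(starts, r.start))
        if n_ref == 0:
            raise ValueError(f"CGI {r.cgi_id} contains no CpG in the "
                             "reference; annotation error")
    for name, calls in sample_calls.items():
        pct = np.full(len(cgi_bed), np.nan)
        info = np.zeros(len(cgi_bed), bool)
        site_cache = {}
        for i, r in enumerate(cgi_bed.itertuples()):
            if r.chrom not in site_cache:
                site_cache[r.chrom] = calls.cpg_site_counts(r.chrom)
            pos, c, t = site_cache[r.chrom]
            lo = np.searchsorted(pos, r.start)
            hi = np.searchsorted(pos, r.end)
            cs, ts = c[lo:hi], t[lo:hi]
            covered = (cs + ts) > 0
            total = int(cs.sum() + ts.sum())
            if covered.sum() >= p.min_covered_cpgs and total >= p.min_total_calls:
                info[i] = True
                pct[i] = 100.0 * cs.sum() / total
        out[name] = pct
        out[f"{name}_informative"] = info
    return out


def classify_cgi_sets(table: pd.DataFrame, params: DmrParams | None = None,
                      oocyte_col: str = "oocyte",
                      sperm_col: str = "sperm") -> dict[str, pd.DataFrame]:
    """Partition CGIs into highly methylated sets and gDMRs.

    Only CGIs informative in both gametes are eligible. Returns a dict of
    DataFrames keyed by: informative, oocyte_high, sperm_high, both_high,
    oocyte_gdmr, sperm_gdmr, gdmr (union).
    """
    p = params or DmrParams()
    for col in (oocyte_col, sperm_col):
        if col not in table.columns:
            raise ValueError(f"missing sample column {col!r}")

    def _inf(col):
        flag = f"{col}_informative"
        if flag in table.columns:
            return table[flag].astype(bool)
        return table[col].notna()

    eligible = table[_inf(oocyte_col) & _inf(sperm_col)]
    oo, sp = eligible[oocyte_col], eligible[sperm_col]
    oocyte_high = eligible[oo >= p.highmeth_min]
    sperm_high = eligible[sp >= p.highmeth_min]
    both_high = eligible[(oo >= p.highmeth_min) & (sp >= p.highmeth_min)]
    oocyte_gdmr = eligible[(oo >= p.hi) & (sp <= p.lo)]
    sperm_gdmr = eligible[(sp >= p.hi) & (oo <= p.lo)]
    gdmr = pd.concat([oocyte_gdmr.assign(gdmr_class="oocyte_methylated"),
                      sperm_gdmr.assign(gdmr_class="sperm_methylated")],
                     ignore_index=True)
    return {"informative": eligible, "oocyte_high": oocyte_high,
            "sperm_high": sperm_high, "both_high": both_high,
            "oocyte_gdmr": oocyte_gdmr, "sperm_gdmr": sperm_gdmr,
            "gdmr": gdmr}


def _gene_location_label(cgi_start, cgi_end, gene, upstream=500) -> str | None:
    """Most specific feature the CGI overlaps within one gene model."""
    es, ee = gene.exon_starts, gene.exon_ends
    if gene.strand == "+":
        first = (es[0], ee[0])
        last = (es[-1], ee[-1])
        prom = (gene.start - upstream, gene.start)
    else:
        first = (es[-1], ee[-1])
        last = (es[0], ee[0])
        prom = (gene.end, gene.end + upstream)

    def _ov(iv):
        return cgi_start < iv[1] and iv[0] < cgi_end

    if _ov(prom) or _ov(first):
        return "promoter_or_first_exon"
    if _ov(last):
        return "last_exon"
    if any(_ov((s, e)) for s, e in zip(es, ee)
           if (s, e) not in (first, last)):
        return "other_exon"
    if _ov((gene.start, gene.end)):
        return "intron"
    return None


def classify_gdmr_location(gdmrs: pd.DataFrame, gene_models: pd.DataFrame,
                           upstream: int = 500) -> pd.Series:
    """Location label per gDMR with promoter/first-exon precedence."""
    if gene_models["exon_starts"].map(len).eq(0).any():
        raise ValueError("gene model without exons")
    order = {lab: i for i, lab in enumerate(LOCATIONS)}
    labels = []
    for r in gdmrs.itertuples():
        best = "intergenic"
        near = gene_models[(gene_models.chrom == r.chrom)
                           & (gene_models.start - upstream < r.end)
                           & (gene_models.end + upstream > r.start)]
        for g in near.itertuples():
            lab = _gene_location_label(r.start, r.end, g, upstream)
            if lab is not None and order[lab] < order[best]:
                best = lab
        labels.append(best)
    return pd.Series(labels, index=gdmrs.index, name="location")


def classify_gdmr_expression_group(gdmrs: pd.DataFrame,
                                   expression: pd.DataFrame,
                                   gene_models: pd.DataFrame) -> pd.Series:
    """Expression quintile (1=top) of the host gene; NA when intergenic or
    the host gene lacks an expression record. A gDMR inside several genes is
    attributed to the highest-expressed host."""
    rec = expression.set_index("gene_id")
    groups = []
    for r in gdmrs.itertuples():
        host = gene_models[(gene_models.chrom == r.chrom)
                           & (gene_models.start < r.end)
                           & (gene_models.end > r.start)]
        if len(host) == 0:
            groups.append(pd.NA)
            continue
        best_g, best_rpkm = None, -1.0
        for g in host.itertuples():
            if g.gene_id in rec.index:
                rpkm = float(rec.loc[g.gene_id, "rpkm"])
                if rpkm > best_rpkm:
                    best_g, best_rpkm = g.gene_id, rpkm
        groups.append(int(rec.loc[best_g, "group"]) if best_g else pd.NA)
    return pd.Series(groups, index=gdmrs.index, dtype="Int64", name="group")


def classify_postfertilization_fate(gdmrs: pd.DataFrame,
                                    blastocyst_col: str = "blastocyst",
                                    esc_col: str | None = "esc",
                                    params: DmrParams | None = None
                                    ) -> pd.DataFrame:
    """Attach fate (resistant/sensitive/NA) and the ESC fate partition.

    Resistant = blastocyst percent >= 20. ESC classes split each fate at
    the 20% line: resistant -> demethylated (<20) vs maintained_or_increased;
    sensitive -> remethylated (>=20) vs low_maintained.
    """
    p = params or DmrParams()
    out = gdmrs.copy()
    bl = out[blastocyst_col] if blastocyst_col in out else pd.Series(
        np.nan, index=out.index)
    fate = np.where(bl.isna(), "NA",
                    np.where(bl >= p.resist_min, "resistant", "sensitive"))
    out["fate"] = fate
    if esc_col is not None and esc_col in out.columns:
        esc = out[esc_col]
        esc_fate = np.full(len(out), "NA", dtype=object)
        res = (fate == "resistant") & esc.notna()
        sen = (fate == "sensitive") & esc.notna()
        esc_fate[res & (esc < p.resist_min)] = "demethylated"
        esc_fate[res & (esc >= p.resist_min)] = "maintained_or_increased"
        esc_fate[sen & (esc >= p.resist_min)] = "remethylated"
        esc_fate[sen & (esc < p.resist_min)] = "low_maintained"
        out["esc_fate"] = esc_fate
    return out


def region_methylation(sample_calls: dict, intervals: pd.DataFrame,
                       one_based_inclusive: bool = False) -> pd.DataFrame:
    """Pooled CpG percent per interval per sample (Table-2-style report).

    ``intervals`` needs chrom/start/end plus an optional name column.
    Intervals printed 1-based inclusive are converted internally when
    ``one_based_inclusive`` is set. Intervals with no covered CpGs get NaN.
    """
    name_col = next((c for c in ("name", "icr_id", "cgi_id", "gene_id")
                     if c in intervals.columns), None)
    out = pd.DataFrame({
        "name": intervals[name_col] if name_col else
        [f"iv{i}" for i in range(len(intervals))],
        "chrom": intervals.chrom,
        "start": intervals.start - (1 if one_based_inclusive else 0),
        "end": intervals.end,
    })
    for sample, calls in sample_calls.items():
        vals = []
        cache = {}
        for r in out.itertuples():
            if r.chrom not in cache:
                cache[r.chrom] = calls.cpg_site_counts(r.chrom)
            pos, c, t = cache[r.chrom]
            lo, hi = np.searchsorted(pos, (r.start, r.end))
            tot = int(c[lo:hi].sum() + t[lo:hi].sum())
            vals.append(100.0 * c[lo:hi].sum() / tot if tot else np.nan)
        out[sample] = vals
    return out


def confirm_gdmrs_external(gdmrs: pd.DataFrame, external: pd.DataFrame,
                           params: DmrParams | None = None,
                           oocyte_col: str = "oocyte",
                           sperm_col: str = "sperm") -> pd.DataFrame:
    """Cross-platform confirmation at the relaxed 75/25 thresholds.

    A gDMR is confirmed when the external table shows the same direction
    with >= confirm_hi in the methylated gamete and <= confirm_lo in the
    other. gDMRs absent from the external table are counted separately in
    ``df.attrs['n_unmatched']``.
    """
    p = params or DmrParams()
    ext = external.set_index("cgi_id")
    confirmed = []
    n_unmatched = 0
    for r in gdmrs.itertuples():
        if r.cgi_id not in ext.index:
            n_unmatched += 1
            confirmed.append(False)
            continue
        eo = ext.loc[r.cgi_id, oocyte_col]
        es = ext.loc[r.cgi_id, sperm_col]
        if pd.isna(eo) or pd.isna(es):
            n_unmatched += 1
            confirmed.append(False)
            continue
        if r.gdmr_class == "oocyte_methylated":
            confirmed.append(eo >= p.confirm_hi and es <= p.confirm_lo)
        else:
            confirmed.append(es >= p.confirm_hi and eo <= p.confirm_lo)
    out = gdmrs[pd.Series(confirmed, index=gdmrs.index)].reset_index(drop=True)
    out.attrs["n_unmatched"] = n_unmatched
    return out


# ------------------------------------------------------------ clone bisulfite

@dataclass
class CloneSet:
    """Clone bisulfite-PCR sequencing data for one locus.

    ``clones``: list of dicts with ``meth`` (tuple of 0/1 per CpG) and
    ``variant_bases`` (tuple of observed bases at the polymorphism sites).
    ``polymorphisms``: list of (position, allele_A_base, allele_B_base).
    """

    locus: str
    clones: list
    polymorphisms: list
    allele_names: tuple[str, str] = ("A", "B")


def allele_resolved_clone_analysis(clone_set: CloneSet) -> dict:
    """Split clones by polymorphism majority vote; percent per allele.

    Percent methylation follows the clone-counting convention
    100 x (methylated CpGs) / (total CpGs), pooled over the allele's
    clones. Clones matching neither allele at a majority of variant sites
    are excluded and counted as ambiguous.
    """
    a_name, b_name = clone_set.allele_names
    tall = {a_name: [0, 0], b_name: [0, 0]}
    n_clones = {a_name: 0, b_name: 0}
    ambiguous = 0
    n_var = len(clone_set.polymorphisms)
    for clone in clone_set.clones:
        votes_a = votes_b = 0
        for (pos, base_a, base_b), obs in zip(clone_set.polymorphisms,
                                              clone["variant_bases"]):
            if obs == base_a:
                votes_a += 1
            elif obs == base_b:
                votes_b += 1
        if votes_a > n_var / 2:
            allele = a_name
        elif votes_b > n_var / 2:
            allele = b_name
        else:
            ambiguous += 1
            continue
        meth = clone["meth"]
        tall[allele][0] += int(sum(meth))
        tall[allele][1] += len(meth)
        n_clones[allele] += 1
    out = {"locus": clone_set.locus, "ambiguous": ambiguous}
    for name in (a_name, b_name):
        m, tot = tall[name]
        out[name] = {"percent": 100.0 * m / tot if tot else None,
                     "n_clones": n_clones[name], "n_cpgs": tot,
                     "n_methylated": m}
    return out
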