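"""Per-cytosine methylation calling from aligned bisulfite tags.

Every reference cytosine under an alignment receives one C (originally
methylated) or T (originally unmethylated) observation; percent methylation
is 100 * C / (C + T). Evidence is read off the original (unconverted) read:

* OT reads report top-strand cytosines directly as C/T;
* OB reads report bottom-strand cytosines (reference G) as C/T at the
  mirrored read position;
* CTOT/CTOB reads are complements of converted strands, so the evidence
  letters are G (methylated) / A (unmethylated).

Sequence context (CpG / CpHpG / CpHpH, H = A, T or C) is derived solely
from the reference, on the cytosine's own strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import FILTERED_REPEAT_CLASSES, Genome, merged_intervals

CONTEXTS = ("CpG", "CpHpG", "CpHpH")


class IntegrityError(RuntimeError):
    """A read base impossible under exact converted-space matching."""


def methylation_percent(c_count: int, t_count: int) -> float:
    """100 * C / (C + T); undefined (raises) at zero depth."""
    depth = c_count + t_count
    if depth < 1:
        raise ValueError("methylation percent undefined at zero depth; "
                         "mark the site non-informative instead")
    return 100.0 * c_count / depth


def classify_context(genome: Genome, chrom: str, pos: int,
                     strand: str) -> str | None:
    """Context of the cytosine at (chrom, pos, strand); None if the
    downstream window runs off the contig or contains N."""
    e = genome.enc(chrom)
    if strand == "+":
        if e[pos] != 1:
            raise ValueError(f"{chrom}:{pos}:+ is not a cytosine")
        n1 = e[pos + 1] if pos + 1 < len(e) else 4
        n2 = e[pos + 2] if pos + 2 < len(e) else 4
        if n1 == 2:
            return "CpG"
        if n1 == 4:
            return None
        if n2 == 2:
            return "CpHpG"
        return None if n2 == 4 else "CpHpH"
    if e[pos] != 2:
        raise ValueError(f"{chrom}:{pos}:- is not a cytosine")
    n1 = e[pos - 1] if pos - 1 >= 0 else 4
    n2 = e[pos - 2] if pos - 2 >= 0 else 4
    if n1 == 1:
        return "CpG"
    if n1 == 4:
        return None
    if n2 == 1:
        return "CpHpG"
    return None if n2 == 4 else "CpHpH"


def context_arrays(genome: Genome, chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised context labels for every position of both strands.

    Returns (ctx_plus, ctx_minus) object arrays holding 'CpG'/'CpHpG'/
    'CpHpH' at cytosine positions and '' elsewhere (or where unclassifiable).
    """
    e = genome.enc(chrom)
    n = len(e)
    pad = np.concatenate([e, [4, 4]])
    ctx_p = np.full(n, "", dtype=object)
    cmask = e == 1
    n1, n2 = pad[1:n + 1], pad[2:n + 2]
    ctx_p[cmask & (n1 == 2)] = "CpG"
    h1 = cmask & (n1 != 2) & (n1 != 4)
    ctx_p[h1 & (n2 == 2)] = "CpHpG"
    ctx_p[h1 & (n2 != 2) & (n2 != 4)] = "CpHpH"
    padl = np.concatenate([[4, 4], e])
    ctx_m = np.full(n, "", dtype=object)
    gmask = e == 2
    p1, p2 = padl[1:n + 1], padl[0:n]
    ctx_m[gmask & (p1 == 1)] = "CpG"
    g1 = gmask & (p1 != 1) & (p1 != 4)
    ctx_m[g1 & (p2 == 1)] = "CpHpG"
    ctx_m[g1 & (p2 != 1) & (p2 != 4)] = "CpHpH"
    return ctx_p, ctx_m


@dataclass
class CallSet:
    """Aligned C/T tallies per reference position, per strand.

    Full-length uint32 arrays per contig keep lookups O(1); the tabular
    per-site view (chrom, pos0, strand, context, c, t, percent) is built on
    demand by :meth:`to_frame`.
    """

    genome: Genome
    c_plus: dict[str, np.ndarray]
    t_plus: dict[str, np.ndarray]
    c_minus: dict[str, np.ndarray]
    t_minus: dict[str, np.ndarray]
    aligned_bases: dict[str, int] = field(default_factory=dict)
    counters: dict = field(default_factory=dict)

    @classmethod
    def empty(cls, genome: Genome) -> "CallSet":
        mk = lambda: {c: np.zeros(len(genome.sequences[c]), dtype=np.uint32)
                      for c in genome.chroms}
        return cls(genome, mk(), mk(), mk(), mk(),
                   {c: 0 for c in genome.chroms})

    @classmethod
    def from_frame(cls, genome: Genome, df: pd.DataFrame) -> "CallSet":
        """Rebuild a CallSet from its tabular dump (chrom,pos,strand,c,t)."""
        cs = cls.empty(genome)
        for chrom, sub in df.groupby("chrom"):
            for strand, carr, tarr in (("+", cs.c_plus[chrom],
                                        cs.t_plus[chrom]),
                                       ("-", cs.c_minus[chrom],
                                        cs.t_minus[chrom])):
                s = sub[sub.strand == strand]
                carr[s.pos.to_numpy()] = s.c.to_numpy()
                tarr[s.pos.to_numpy()] = s.t.to_numpy()
            cs.aligned_bases[chrom] = int(sub.c.sum() + sub.t.sum())
        return cs

    # ------------------------------------------------------------ accessors
    def site(self, chrom: str, pos: int, strand: str) -> tuple[int, int]:
        if strand == "+":
            return int(self.c_plus[chrom][pos]), int(self.t_plus[chrom][pos])
        return int(self.c_minus[chrom][pos]), int(self.t_minus[chrom][pos])

    def cpg_site_counts(self, chrom: str):
        """Merged counts per CpG dinucleotide (top C + bottom C)."""
        p = self.genome.cpg_starts(chrom)
        c = self.c_plus[chrom][p] + self.c_minus[chrom][p + 1]
        t = self.t_plus[chrom][p] + self.t_minus[chrom][p + 1]
        return p, c.astype(np.int64), t.astype(np.int64)

    def cpg_cytosine_counts(self, chrom: str):
        """Per-strand counts at CpG cytosines: (positions, strand_is_minus,
        c, t) with the two cytosines of each dinucleotide kept separate."""
        p = self.genome.cpg_starts(chrom)
        pos = np.concatenate([p, p + 1])
        minus = np.concatenate([np.zeros(len(p), bool), np.ones(len(p), bool)])
        c = np.concatenate([self.c_plus[chrom][p], self.c_minus[chrom][p + 1]])
        t = np.concatenate([self.t_plus[chrom][p], self.t_minus[chrom][p + 1]])
        return pos, minus, c.astype(np.int64), t.astype(np.int64)

    def to_frame(self, chroms=None, min_depth: int = 1,
                 contexts=None) -> pd.DataFrame:
        chroms = list(self.genome.chroms) if chroms is None else chroms
        parts = []
        for chrom in chroms:
            ctx_p, ctx_m = context_arrays(self.genome, chrom)
            for strand, carr, tarr, ctx in (
                    ("+", self.c_plus[chrom], self.t_plus[chrom], ctx_p),
                    ("-", self.c_minus[chrom], self.t_minus[chrom], ctx_m)):
                depth = carr.astype(np.int64) + tarr
                sel = depth >= min_depth
                sel &= np.asarray(ctx, dtype=object) != ""
                pos = np.flatnonzero(sel)
                if len(pos) == 0:
                    continue
                sub = pd.DataFrame({
                    "chrom": chrom, "pos": pos, "strand": strand,
                    "context": ctx[pos], "c": carr[pos].astype(np.int64),
                    "t": tarr[pos].astype(np.int64)})
                parts.append(sub)
        if not parts:
            return pd.DataFrame(columns=["chrom", "pos", "strand", "context",
                                         "c", "t", "percent"])
        df = pd.concat(parts, ignore_index=True)
        if contexts is not None:
            df = df[df.context.isin(contexts)].reset_index(drop=True)
        df["percent"] = 100.0 * df.c / (df.c + df.t)
        return df

    def write_tsv(self, path, **kw) -> None:
        self.to_frame(**kw).to_csv(path, sep="\t", index=False)

    def write_bedgraph(self, path, contexts=("CpG",), min_depth: int = 1) -> None:
        df = self.to_frame(contexts=contexts, min_depth=min_depth)
        with open(path, "w") as fh:
            for r in df.itertuples():
                fh.write(f"{r.chrom}\t{r.pos}\t{r.pos + 1}\t{r.percent:.6g}\n")


_EXPECT = {  # bs_strand -> (ref base code, meth read code, unmeth read code,
             #              tally strand, read is minus-oriented)
    "OT": (1, 1, 3, "+", False),
    "OB": (2, 1, 3, "-", True),
    "CTOB": (2, 2, 0, "-", False),
    "CTOT": (1, 2, 0, "+", True),
}


def tally_cytosines(alignments: pd.DataFrame, genome: Genome,
                    reads: dict[str, str] | None = None) -> CallSet:
    """Accumulate C/T evidence from unique alignments into a CallSet.

    ``alignments`` must carry the aligned (trimmed, unconverted) sequence in
    a ``seq`` column, as produced by :func:`~gametemeth.align.align_reads`;
    alternatively pass ``reads`` mapping read_id -> sequence.
    """
    cs = CallSet.empty(genome)
    if "seq" not in alignments.columns:
        if reads is None:
            raise IntegrityError("alignments lack sequences and no reads "
                                 "mapping was provided")
        alignments = alignments.assign(
            seq=alignments.read_id.map(reads))
        if alignments.seq.isna().any():
            raise IntegrityError("read_id absent from reads mapping")
    from .genome import encode

    for (chrom, bs, L), sub in alignments.groupby(
            ["chrom", "bisulfite_strand", "length"], sort=False):
        e = genome.enc(chrom)
        starts = sub.start.to_numpy()
        renc = encode("".join(sub.seq)).reshape(len(sub), L)
        refbase, meth_code, unmeth_code, strand, rev = _EXPECT[bs]
        idx = starts[:, None] + np.arange(L)
        refwin = e[idx]
        sites = refwin == refbase
        rb = renc[:, ::-1] if rev else renc
        obs = rb[sites]
        positions = idx[sites]
        is_meth = obs == meth_code
        is_unmeth = obs == unmeth_code
        if not np.all(is_meth | is_unmeth):
            raise IntegrityError(
                f"unexpected read base at reference cytosine "
                f"({chrom}, {bs}); alignment/strand bookkeeping is broken")
        carr = cs.c_plus[chrom] if strand == "+" else cs.c_minus[chrom]
        tarr = cs.t_plus[chrom] if strand == "+" else cs.t_minus[chrom]
        np.add.at(carr, positions[is_meth], 1)
        np.add.at(tarr, positions[is_unmeth], 1)
        cs.aligned_bases[chrom] = cs.aligned_bases.get(chrom, 0) + len(sub) * L
    return cs


@dataclass
class ConversionStats:
    failure_rate: float | None
    n_sites: int
    n_calls: int
    defined: bool = True


def estimate_conversion_failure(calls: CallSet,
                                lambda_name: str | None = None
                                ) -> ConversionStats:
    """Pooled C:(C+T) over all cytosines of the unmethylated spike-in."""
    lam = lambda_name or calls.genome.lambda_name
    if lam is None or lam not in calls.c_plus:
        return ConversionStats(None, 0, 0, defined=False)
    c = int(calls.c_plus[lam].sum() + calls.c_minus[lam].sum())
    t = int(calls.t_plus[lam].sum() + calls.t_minus[lam].sum())
    n_sites = int(((calls.c_plus[lam] + calls.t_plus[lam]) > 0).sum()
                  + ((calls.c_minus[lam] + calls.t_minus[lam]) > 0).sum())
    if c + t == 0:
        return ConversionStats(None, 0, 0, defined=False)
    return ConversionStats(c / (c + t), n_sites, c + t)


@dataclass
class CoverageSummary:
    fraction_ge1: float
    fraction_ge5: float
    mean_depth: float            # aligned bases / analysis genome length
    mean_cpg_depth: float        # calls per genomic CpG cytosine
    per_chrom: pd.DataFrame = None


def summarize_coverage(calls: CallSet, genome: Genome | None = None,
                       exclude_repeat_classes=FILTERED_REPEAT_CLASSES
                       ) -> CoverageSummary:
    """Table-1-style coverage: fraction of genomic CpG cytosines covered
    >=1x / >=5x and mean read depth, on analysis chromosomes with the
    filtered repeat classes excluded from the denominator."""
    genome = genome or calls.genome
    merged = merged_intervals(
        genome.repeats[genome.repeats.family.isin(exclude_repeat_classes)])
    rows = []
    tot_sites = tot_1 = tot_5 = tot_depth = 0
    tot_bases = tot_len = 0
    for chrom in genome.analysis_chroms:
        pos, minus, c, t = calls.cpg_cytosine_counts(chrom)
        keep = np.ones(len(pos), bool)
        if chrom in merged:
            ms, me = merged[chrom]
            if len(ms):
                i = np.searchsorted(me, pos, side="right")
                inside = (i < len(ms)) & (ms[np.minimum(i, len(ms) - 1)] <= pos)
                keep &= ~inside
        depth = (c + t)[keep]
        rows.append((chrom, len(depth), float((depth >= 1).mean()) if
                     len(depth) else 0.0,
                     float((depth >= 5).mean()) if len(depth) else 0.0,
                     float(depth.mean()) if len(depth) else 0.0))
        tot_sites += len(depth)
        tot_1 += int((depth >= 1).sum())
        tot_5 += int((depth >= 5).sum())
        tot_depth += int(depth.sum())
        tot_bases += calls.aligned_bases.get(chrom, 0)
        tot_len += len(genome.sequences[chrom])
    per_chrom = pd.DataFrame(rows, columns=["chrom", "n_cpg", "ge1", "ge5",
                                            "cpg_depth"])
    if tot_sites == 0:
        return CoverageSummary(0.0, 0.0, 0.0, 0.0, per_chrom)
    return CoverageSummary(tot_1 / tot_sites, tot_5 / tot_sites,
                           tot_bases / tot_len if tot_len else 0.0,
                           tot_depth / tot_sites, per_chrom)


def context_methylation_ratio(calls: CallSet, chroms=None) -> dict:
    """Pooled C/(C+T) per sequence context (CpG, CpHpG, CpHpH).

    Contexts with zero calls map to None.
    """
    genome = calls.genome
    chroms = genome.analysis_chroms if chroms is None else chroms
    agg = {k: [0, 0] for k in CONTEXTS}
    for chrom in chroms:
        ctx_p, ctx_m = context_arrays(genome, chrom)
        for ctx_arr, carr, tarr in ((ctx_p, calls.c_plus[chrom],
                                     calls.t_plus[chrom]),
                                    (ctx_m, calls.c_minus[chrom],
                                     calls.t_minus[chrom])):
            for k in CONTEXTS:
                sel = ctx_arr == k
                agg[k][0] += int(carr[sel].sum())
                agg[k][1] += int(tarr[sel].sum())
    out = {}
    for k, (c, t) in agg.items():
        out[k] = c / (c + t) if c + t else None
    return out
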