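"""Synthetic genomes, ground-truth methylomes, and read simulation.

The generator family emulates the statistical structure of mouse gamete
methylomes so that every downstream analysis has a known ground truth:

* oocyte-like methylomes are bimodal, with gene-body methylation that rises
  with the gene's expression rank and hypomethylated regions near the TSS;
* sperm-like methylomes are globally hypermethylated with a steep decline
  at CpG-rich sequence (CGIs) and expression-coupled promoter dips;
* Dnmt3L-null ("ko") oocyte methylomes are globally hypomethylated except
  for partial methylation retained at LINE/LTR retroelements;
* blastocyst and ESC methylomes encode the post-fertilization fate of each
  planted germline DMR (demethylation-resistant vs sensitive, and ESC
  re-/de-methylation);
* an unmethylated lambda spike-in contig supports conversion-failure QC.

Bisulfite conversion is per-cytosine Bernoulli: a cytosine with methylation
probability m is read as C with probability m + (1-m)*eps, where eps is the
conversion failure rate, otherwise as T.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import Genome, decode, LAMBDA

log = logging.getLogger(__name__)

SAMPLE_LABELS = ("oocyte", "sperm", "dnmt3l_ko", "blastocyst", "esc", "custom")

CGI_CLASSES = ("both_low", "oocyte_gdmr", "sperm_gdmr", "both_high",
               "oocyte_high_only", "sperm_high_only", "intermediate")

#: mitochondrial CpG methylation regimes per sample
_CHRM_LEVEL = {"oocyte": 0.066, "sperm": 0.147, "dnmt3l_ko": 0.044,
               "blastocyst": 0.013, "esc": 0.021}

_REPEAT_UNIT_LEN = {"LINE": 3000, "SINE": 250, "LTR": 500, "DNA": 800,
                    "simple_repeat": 150, "low_complexity": 120,
                    "satellite": 960}


class GenomeSizingError(ValueError):
    """Requested features do not fit on the requested chromosomes."""


@dataclass
class SyntheticGenomeSpec:
    n_autosomes: int = 3
    chrom_length: int = 600_000
    n_genes: int = 120
    exons_per_gene: int = 3
    n_cgis: int = 120
    cgi_length_range: tuple[int, int] = (250, 900)
    repeat_fractions: dict = field(default_factory=lambda: {
        "LINE": 0.10, "SINE": 0.06, "LTR": 0.05, "DNA": 0.02,
        "simple_repeat": 0.015, "low_complexity": 0.01, "satellite": 0.01,
    })
    include_chrM: bool = True
    include_chrY: bool = True
    include_lambda: bool = True
    gc_content: float = 0.42
    cpg_depletion: float = 0.75
    cgi_placement_mix: tuple[float, float, float] = (0.40, 0.35, 0.25)
    # class proportions follow the observed composition of the mouse CGI
    # universe (gDMRs ~5.8%/1.5%, highly methylated 8.7%/3.6%, 1.6% in both)
    cgi_class_fractions: dict = field(default_factory=lambda: {
        "oocyte_gdmr": 0.058, "sperm_gdmr": 0.015, "both_high": 0.016,
        "oocyte_high_only": 0.013, "sperm_high_only": 0.005,
        "intermediate": 0.030,
    })
    resistant_fraction: dict = field(default_factory=lambda: {
        "oocyte_gdmr": 0.60, "sperm_gdmr": 0.15})
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if self.chrom_length < 20_000:
            raise GenomeSizingError("chromosomes shorter than 20 kb cannot "
                                    "host the requested feature set")
        lo, hi = self.cgi_length_range
        if not (50 <= lo <= hi):
            raise ValueError("bad cgi_length_range")
        genes_per_chrom = -(-self.n_genes // self.n_autosomes)
        if genes_per_chrom * 12_000 > self.chrom_length:
            raise GenomeSizingError(
                f"{self.n_genes} genes do not fit on {self.n_autosomes} "
                f"chromosomes of {self.chrom_length} bp")
        if sum(self.cgi_class_fractions.values()) > 1:
            raise ValueError("cgi_class_fractions sum above 1")


def _random_enc(rng, length: int, gc: float) -> np.ndarray:
    cum = np.cumsum([(1 - gc) / 2, gc / 2, gc / 2])
    return np.searchsorted(cum, rng.random(length), side="right").astype(np.uint8)


def _deplete_cpg(rng, enc: np.ndarray, depletion: float) -> None:
    """Transition-mutate a fraction of CpG dinucleotides (deamination mimic)."""
    pos = np.flatnonzero((enc[:-1] == 1) & (enc[1:] == 2))
    mut = pos[rng.random(len(pos)) < depletion]
    coin = rng.random(len(mut)) < 0.5
    enc[mut[coin]] = 3        # C -> T
    enc[mut[~coin] + 1] = 0   # G -> A


def _cgi_enc(rng, length: int) -> np.ndarray:
    """CpG-rich segment: GC-rich background with CG planted every ~6-14 nt."""
    seg = _random_enc(rng, length, 0.55)
    step = int(rng.integers(6, 14))
    i = int(rng.integers(0, step))
    while i < length - 1:
        seg[i], seg[i + 1] = 1, 2
        i += step + int(rng.integers(0, 3))
    return seg


def generate_genome(spec: SyntheticGenomeSpec) -> Genome:
    """Build a synthetic genome with gene models, CGIs, repeats and ICRs.

    Deterministic for a fixed ``spec.seed``. Raises
    :class:`GenomeSizingError` when the requested features cannot fit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    enc_seqs: dict[str, np.ndarray] = {}
    autosomes = [f"chr{i + 1}" for i in range(spec.n_autosomes)]
    for c in autosomes:
        e = _random_enc(rng, spec.chrom_length, spec.gc_content)
        _deplete_cpg(rng, e, spec.cpg_depletion)
        enc_seqs[c] = e

    # ---------------- gene models
    genes = []
    per_chrom = np.array_split(np.arange(spec.n_genes), spec.n_autosomes)
    for c, idxs in zip(autosomes, per_chrom):
        cursor = 3000
        for gi in idxs:
            glen = int(np.clip(rng.lognormal(np.log(6500), 0.35), 3500, 14000))
            gap = int(rng.uniform(2500, 6000))
            if cursor + glen + gap > spec.chrom_length - 3000:
                raise GenomeSizingError(
                    f"gene g{gi:04d} does not fit on {c}; increase "
                    "chrom_length or reduce n_genes")
            start, end = cursor, cursor + glen
            strand = "+" if rng.random() < 0.5 else "-"
            k = max(1, spec.exons_per_gene)
            if k == 1:
                es, ee = (start,), (end,)
            else:
                first = (start, start + 300)
                last = (end - 300, end)
                mids = []
                for j in range(1, k - 1):
                    mstart = start + 300 + j * (glen - 800) // (k - 1)
                    mids.append((mstart, mstart + 200))
                exons = [first] + mids + [last]
                es = tuple(s for s, _ in exons)
                ee = tuple(e for _, e in exons)
            genes.append(dict(gene_id=f"g{gi:04d}", chrom=c, start=start,
                              end=end, strand=strand, exon_starts=es,
                              exon_ends=ee))
            cursor = end + gap
    genes = pd.DataFrame(genes)
    genes["expression_oocyte"] = rng.lognormal(1.0, 1.4, len(genes))
    genes["expression_sperm"] = rng.lognormal(1.0, 1.4, len(genes))

    # ---------------- CpG islands
    n_prom = int(round(spec.n_cgis * spec.cgi_placement_mix[0]))
    n_intra = int(round(spec.n_cgis * spec.cgi_placement_mix[1]))
    n_inter = spec.n_cgis - n_prom - n_intra
    placements = (["promoter"] * n_prom + ["intragenic"] * n_intra
                  + ["intergenic"] * n_inter)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in autosomes}

    def _free(chrom, s, e):
        return s >= 0 and e <= len(enc_seqs[chrom]) and not any(
            s < oe and os_ < e for os_, oe in occupied[chrom])

    cgi_rows = []
    prom_genes = genes.sample(frac=1.0, random_state=int(rng.integers(2**31)))
    prom_iter = iter(prom_genes.itertuples())
    for ci, placement in enumerate(placements):
        length = int(rng.integers(*spec.cgi_length_range))
        placed = False
        for _attempt in range(200):
            if placement == "promoter":
                try:
                    g = next(prom_iter)
                except StopIteration:
                    placement = "intergenic"
                    continue
                tss = g.start if g.strand == "+" else g.end - 1
                s = tss - length // 2
            elif placement == "intragenic":
                g = genes.iloc[int(rng.integers(len(genes)))]
                lo, hi = g.start + 800, g.end - 800 - length
                if hi <= lo:
                    continue
                s = int(rng.integers(lo, hi))
            else:
                c = autosomes[int(rng.integers(len(autosomes)))]
                s = int(rng.integers(2000, len(enc_seqs[c]) - 2000 - length))
            chrom = g.chrom if placement != "intergenic" else c
            if _free(chrom, s, s + length):
                enc_seqs[chrom][s:s + length] = _cgi_enc(rng, length)
                occupied[chrom].append((s, s + length))
                cgi_rows.append(dict(cgi_id=f"cgi{ci:05d}", chrom=chrom,
                                     start=s, end=s + length,
                                     placement=placement))
                placed = True
                break
        if not placed:
            raise GenomeSizingError(f"could not place CGI {ci}; genome too "
                                    "crowded for n_cgis")
    cgis = pd.DataFrame(cgi_rows)

    # methylation-class plan per CGI
    classes = list(spec.cgi_class_fractions)
    probs = np.array([spec.cgi_class_fractions[k] for k in classes])
    draw = rng.random(len(cgis))
    edges = np.cumsum(probs)
    cls_idx = np.searchsorted(edges, draw, side="right")
    cgis["meth_class"] = [classes[i] if i < len(classes) else "both_low"
                          for i in cls_idx]
    fate, esc_fate = [], []
    for mc in cgis["meth_class"]:
        if mc in ("oocyte_gdmr", "sperm_gdmr"):
            res = rng.random() < spec.resistant_fraction[mc]
            fate.append("resistant" if res else "sensitive")
            if res:
                esc_fate.append("demethylated" if rng.random() < 0.26
                                else "maintained_or_increased")
            elif mc == "sperm_gdmr":
                esc_fate.append("remethylated" if rng.random() < 0.76
                                else "low_maintained")
            else:
                esc_fate.append("low_maintained" if rng.random() < 0.81
                                else "remethylated")
        else:
            fate.append("NA")
            esc_fate.append("NA")
    cgis["fate"] = fate
    cgis["esc_fate"] = esc_fate

    # ICR-like intervals: maternal at promoter oocyte-gDMRs, paternal intergenic
    mat = cgis[(cgis.meth_class == "oocyte_gdmr")
               & (cgis.placement == "promoter")].head(4)
    pat = cgis[(cgis.meth_class == "sperm_gdmr")
               & (cgis.placement == "intergenic")].head(2)
    forced = mat.index.union(pat.index)
    newly = cgis.loc[forced, "fate"] != "resistant"
    cgis.loc[forced, "fate"] = "resistant"
    cgis.loc[forced[newly], "esc_fate"] = "maintained_or_increased"
    icr_rows = []
    for j, r in enumerate(pd.concat([mat, pat]).itertuples()):
        parent = "maternal" if r.meth_class == "oocyte_gdmr" else "paternal"
        icr_rows.append(dict(icr_id=f"icr{j:02d}", chrom=r.chrom,
                             start=r.start, end=r.end, parent=parent,
                             cgi_id=r.cgi_id))
    icrs = pd.DataFrame(icr_rows, columns=["icr_id", "chrom", "start", "end",
                                           "parent", "cgi_id"])

    # ---------------- repeats
    consensus = {}
    for fam in ("LINE", "SINE", "LTR", "DNA"):
        e = _random_enc(rng, _REPEAT_UNIT_LEN[fam], 0.45)
        _deplete_cpg(rng, e, spec.cpg_depletion)   # TEs are CpG-depleted too
        consensus[fam] = e
    sat_unit = _random_enc(rng, 120, 0.45)
    rep_rows = []
    total_auto = spec.n_autosomes * spec.chrom_length
    for fam, frac in spec.repeat_fractions.items():
        target = frac * total_auto
        placed_bp = 0
        guard = 0
        while placed_bp < target and guard < 10_000:
            guard += 1
            c = autosomes[int(rng.integers(len(autosomes)))]
            if fam in consensus:
                unit = consensus[fam]
                copy = unit.copy()
                nmut = int(0.12 * len(copy))
                mpos = rng.integers(0, len(copy), nmut)
                copy[mpos] = (copy[mpos] + rng.integers(1, 4, nmut)) % 4
            elif fam == "simple_repeat":
                u = _random_enc(rng, int(rng.integers(2, 6)), 0.5)
                reps = int(np.ceil(_REPEAT_UNIT_LEN[fam] / len(u)))
                copy = np.tile(u, reps)[:_REPEAT_UNIT_LEN[fam]]
            elif fam == "low_complexity":
                base = int(rng.integers(0, 4))
                copy = np.full(_REPEAT_UNIT_LEN[fam], base, np.uint8)
                sprinkle = rng.integers(0, len(copy), len(copy) // 10)
                copy[sprinkle] = rng.integers(0, 4, len(sprinkle)).astype(np.uint8)
            else:  # satellite: verbatim tandem copies of one genome-wide unit
                copy = np.tile(sat_unit, _REPEAT_UNIT_LEN[fam] // 120)
            L = len(copy)
            s = int(rng.integers(2000, len(enc_seqs[c]) - 2000 - L))
            if not _free(c, s, s + L):
                continue
            enc_seqs[c][s:s + L] = copy
            occupied[c].append((s, s + L))
            rep_rows.append(dict(chrom=c, start=s, end=s + L, family=fam))
            placed_bp += L
    repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "family"])

    # ---------------- extra contigs
    if spec.include_chrM:
        enc_seqs["chrM"] = _random_enc(rng, 16_000, 0.38)
    if spec.include_chrY:
        e = _random_enc(rng, 60_000, spec.gc_content)
        _deplete_cpg(rng, e, spec.cpg_depletion)
        enc_seqs["chrY"] = e
    lam = None
    if spec.include_lambda:
        lam_enc = _random_enc(rng, 20_000, 0.50)
        assert int((lam_enc == 1).sum() + (lam_enc == 2).sum()) >= 500
        enc_seqs[LAMBDA] = lam_enc
        lam = LAMBDA

    sequences = {c: decode(e) for c, e in enc_seqs.items()}
    g = Genome(sequences, genes, cgis, repeats, icrs, lambda_name=lam,
               meta={"spec": {k: v for k, v in asdict(spec).items()
                              if not isinstance(v, dict)}})
    _check_cgi_density(g)
    return g


def _check_cgi_density(g: Genome) -> None:
    bg_cg = bg_len = 0
    for c in [c for c in g.chroms if c.startswith("chr") and c not in
              ("chrM", "chrY")]:
        bg_cg += len(g.cpg_starts(c))
        bg_len += len(g.sequences[c])
    background = bg_cg / bg_len
    for r in g.cgis.itertuples():
        seq = g.sequences[r.chrom][r.start:r.end]
        d = seq.count("CG") / (r.end - r.start)
        if d < 3 * background:
            raise AssertionError(
                f"{r.cgi_id} density {d:.4f} below 3x background "
                f"{background:.4f}")


# ===================================================================== methylome

@dataclass
class MethylomeParams:
    expression_coupling: float = 0.75
    body_floor: float = 0.15
    tss_dip: float = 0.12
    cgi_hypo_in_sperm: float = 0.05
    retro_partial_in_ko: float = 0.40
    noncpg_rate: float | None = None   # default: 0.03 for oocyte, 0 otherwise
    constant: float | None = None      # for sample_label == "custom"
    site_noise: float = 0.02
    seed: int = 0


@dataclass
class TrueMethylome:
    """Per-cytosine methylation probability, full-length arrays per strand."""

    sample_label: str
    levels: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (m_plus, m_minus)

    def m(self, chrom: str, pos: int, strand: str) -> float:
        mp, mm = self.levels[chrom]
        return float(mp[pos] if strand == "+" else mm[pos])

    def to_tsv(self, genome: Genome, path) -> None:
        from .calling import context_arrays

        with open(path, "w") as fh:
            fh.write("chrom\tpos0\tstrand\tcontext\tm\n")
            for chrom, (mp, mm) in self.levels.items():
                ctx_p, ctx_m = context_arrays(genome, chrom)
                e = genome.enc(chrom)
                for p in np.flatnonzero(e == 1):
                    fh.write(f"{chrom}\t{p}\t+\t{ctx_p[p]}\t{mp[p]:.4f}\n")
                for p in np.flatnonzero(e == 2):
                    fh.write(f"{chrom}\t{p}\t-\t{ctx_m[p]}\t{mm[p]:.4f}\n")


def _rank_pct(values: pd.Series) -> pd.Series:
    """Percentile of the expression rank, 1.0 = most expressed."""
    return values.rank(method="average") / len(values)


def generate_true_methylome(genome: Genome, sample_label: str,
                            params: MethylomeParams | None = None
                            ) -> TrueMethylome:
    """Assign every genomic cytosine its true methylation probability."""
    if sample_label not in SAMPLE_LABELS:
        raise ValueError(f"unknown sample_label {sample_label!r}; expected "
                         f"one of {SAMPLE_LABELS}")
    p = params or MethylomeParams()
    if sample_label == "custom" and p.constant is None:
        raise ValueError("sample_label='custom' requires params.constant")
    rng = np.random.default_rng(p.seed)
    rank_oo = dict(zip(genome.genes.gene_id,
                       _rank_pct(genome.genes.expression_oocyte)))
    rank_sp = dict(zip(genome.genes.gene_id,
                       _rank_pct(genome.genes.expression_sperm)))
    ncrate = p.noncpg_rate
    if ncrate is None:
        ncrate = 0.03 if sample_label == "oocyte" else 0.0

    levels = {}
    for chrom in genome.chroms:
        e = genome.enc(chrom)
        n = len(e)
        m_plus = np.zeros(n, dtype=np.float32)
        m_minus = np.zeros(n, dtype=np.float32)
        if chrom == genome.lambda_name:
            levels[chrom] = (m_plus, m_minus)
            continue
        if sample_label == "custom":
            m_plus[e == 1] = p.constant
            m_minus[e == 2] = p.constant
            levels[chrom] = (m_plus, m_minus)
            continue

        sites = genome.cpg_starts(chrom)   # CpG dinucleotide starts
        v = _cpg_site_values(genome, chrom, sites, sample_label, p, rng,
                             rank_oo, rank_sp)
        if chrom == "chrM":
            v[:] = _CHRM_LEVEL[sample_label]
        m_plus[sites] = v
        m_minus[sites + 1] = v
        # non-CpG cytosines
        is_c = e == 1
        is_g = e == 2
        cpg_c = np.zeros(n, bool)
        cpg_c[sites] = True
        cpg_g = np.zeros(n, bool)
        cpg_g[sites + 1] = True
        m_plus[is_c & ~cpg_c] = ncrate
        m_minus[is_g & ~cpg_g] = ncrate
        levels[chrom] = (m_plus, m_minus)
    return TrueMethylome(sample_label, levels)


_CGI_VALUE = {
    # meth_class -> (oocyte, sperm) target levels
    "both_low": (0.04, 0.04), "oocyte_gdmr": (0.93, 0.05),
    "sperm_gdmr": (0.05, 0.93), "both_high": (0.90, 0.90),
    "oocyte_high_only": (0.90, 0.45), "sperm_high_only": (0.45, 0.90),
    "intermediate": (0.50, 0.50),
}


def _cpg_site_values(genome, chrom, sites, sample, p, rng, rank_oo, rank_sp):
    """True methylation per CpG site (value shared by both strands)."""
    ns = len(sites)
    noise = rng.normal(0, p.site_noise, ns)

    if sample == "oocyte":
        v = 0.05 + rng.uniform(0, 0.04, ns)
    elif sample == "sperm":
        from .profiles import cpg_density_track

        d = cpg_density_track(genome, chrom)[sites]
        v = np.clip(0.88 - np.maximum(0.0, d - 0.035) * (0.83 / 0.060),
                    0.05, 0.88)
    elif sample == "dnmt3l_ko":
        v = 0.03 + rng.uniform(0, 0.03, ns)
    elif sample == "blastocyst":
        v = 0.18 + rng.uniform(0, 0.08, ns)
    else:  # esc
        v = 0.65 + rng.uniform(0, 0.15, ns)

    genes = genome.genes[genome.genes.chrom == chrom]
    if sample in ("oocyte", "sperm"):
        for g in genes.itertuples():
            body = (sites >= g.start) & (sites < g.end)
            tss = g.start if g.strand == "+" else g.end - 1
            prom = (sites >= tss - 500) & (sites < tss + 500)
            if sample == "oocyte":
                rp = rank_oo[g.gene_id]
                level = np.clip(p.body_floor + p.expression_coupling * rp
                                + rng.normal(0, 0.05), 0.02, 0.97)
                v[body] = level
                v[prom] = p.tss_dip + rng.uniform(0, 0.05)
            else:
                rp = rank_sp[g.gene_id]
                # weak positive body coupling, clear negative promoter coupling
                v[body] = np.clip(v[body] + 0.08 * (rp - 0.5)
                                  + rng.normal(0, 0.08), 0.02, 0.97)
                v[prom] = np.clip(0.90 - 0.65 * rp + rng.normal(0, 0.12),
                                  0.04, 0.93)
    if sample == "dnmt3l_ko":
        retro = genome.repeats[(genome.repeats.chrom == chrom)
                               & genome.repeats.family.isin(["LINE", "LTR"])]
        for r in retro.itertuples():
            mask = (sites >= r.start) & (sites < r.end)
            v[mask] = p.retro_partial_in_ko + rng.normal(0, 0.04)

    # CGIs override everything positional; their class defines both gametes
    for r in genome.cgis[genome.cgis.chrom == chrom].itertuples():
        mask = (sites >= r.start) & (sites < r.end)
        if not mask.any():
            continue
        oo, sp = _CGI_VALUE[r.meth_class]
        if sample == "oocyte":
            val = oo if oo > 0.2 else 0.04
        elif sample == "sperm":
            val = sp if sp > 0.2 else p.cgi_hypo_in_sperm
        elif sample == "dnmt3l_ko":
            val = 0.04   # maternal marks are Dnmt3L-dependent
        elif sample == "blastocyst":
            if r.fate == "resistant":
                val = float(rng.uniform(0.25, 0.60))
            elif r.fate == "sensitive":
                val = float(rng.uniform(0.02, 0.12))
            else:
                val = 0.25 if max(oo, sp) > 0.8 else 0.05
        else:  # esc
            val = {"demethylated": float(rng.uniform(0.03, 0.15)),
                   "maintained_or_increased": float(rng.uniform(0.45, 0.80)),
                   "remethylated": float(rng.uniform(0.30, 0.50)),
                   "low_maintained": float(rng.uniform(0.03, 0.15)),
                   "NA": 0.60 if max(oo, sp) > 0.8 else 0.08,
                   }[r.esc_fate]
        v[mask] = val
    return np.clip(v + noise, 0.0, 1.0)


# ===================================================================== reads

@dataclass
class ReadSimParams:
    protocol: str = "methylc"          # methylc | wba | pbat
    read_length: int | None = None     # default 76; raw pbat reads are 52 nt
    depth: float = 10.0
    failure_rate: float = 0.01
    duplicate_rate: float = 0.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.protocol not in ("methylc", "wba", "pbat"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.read_length is None:
            self.read_length = 52 if self.protocol == "pbat" else 76
        if not 0 <= self.failure_rate <= 1:
            raise ValueError("failure_rate must be in [0,1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length < 32:
            raise ValueError("read_length must be >= 32")


_PROTOCOL_STRANDS = {"methylc": ("OT", "OB"),
                     "wba": ("OT", "OB", "CTOT", "CTOB"),
                     "pbat": ("CTOT", "CTOB")}


@dataclass
class SimulatedLibrary:
    reads: list          # (read_id, sequence)
    n_unique_fragments: dict[str, int]
    params: ReadSimParams

    def write_fastq(self, path) -> None:
        from .genome import write_fastq

        write_fastq(self.reads, path)


def simulate_bisulfite_reads(genome: Genome, methylome: TrueMethylome,
                             params: ReadSimParams) -> SimulatedLibrary:
    """Draw bisulfite reads from the true methylome.

    Fragments start uniformly at random; each cytosine is emitted as C with
    probability m + (1-m)*eps. ``duplicate_rate`` re-emits already-drawn
    fragments verbatim (PCR duplicates share their conversion outcome).
    Read names encode the true origin: sim|chrom|start|bs_strand|serial.
    """
    rng = np.random.default_rng(params.seed)
    eps = params.failure_rate
    L = params.read_length
    strands = _PROTOCOL_STRANDS[params.protocol]
    reads: list[tuple[str, str]] = []
    n_unique: dict[str, int] = {}

    for chrom in genome.chroms:
        clen = len(genome.sequences[chrom])
        if clen < L:
            continue
        n_total = int(round(params.depth * clen / L))
        if n_total == 0:
            warnings.warn(f"depth {params.depth} yields zero reads on {chrom}")
            n_unique[chrom] = 0
            continue
        n_dup = int(round(n_total * params.duplicate_rate))
        n_uni = n_total - n_dup
        n_unique[chrom] = n_uni
        starts = rng.integers(0, clen - L + 1, n_uni)
        bs = rng.integers(0, len(strands), n_uni)
        e = genome.enc(chrom)
        mp, mm = methylome.levels[chrom]
        chrom_reads: list[tuple[str, str]] = [None] * n_uni
        serial = 0
        for si, bs_name in enumerate(strands):
            sel = np.flatnonzero(bs == si)
            if len(sel) == 0:
                continue
            sub = np.sort(starts[sel])
            idx = sub[:, None] + np.arange(L)
            S = e[idx]
            marr = mp[idx] if bs_name in ("OT", "CTOT") else mm[idx]
            u = rng.random(S.shape)
            meth = u < (marr + (1.0 - marr) * eps)
            out = S.copy()
            if bs_name in ("OT", "CTOT"):
                out[(S == 1) & ~meth] = 3          # unmethylated C -> T
            else:
                out[(S == 2) & ~meth] = 0          # bottom-strand C -> T (G->A image)
            if params.error_rate > 0:
                err = rng.random(out.shape) < params.error_rate
                out[err] = (out[err] + rng.integers(1, 4, int(err.sum()))) % 4
            if bs_name in ("CTOT", "OB"):          # minus-orientation reads
                out = (3 - out)[:, ::-1]
            txt = decode(out.ravel())
            for row_i, s0 in enumerate(sub):
                rid = f"sim|{chrom}|{s0}|{bs_name}|{serial}"
                chrom_reads[serial] = (rid, txt[row_i * L:(row_i + 1) * L])
                serial += 1
        reads.extend(chrom_reads)
        if n_dup:
            picks = rng.integers(0, n_uni, n_dup)
            for di, k in enumerate(picks):
                rid, seq = chrom_reads[k]
                reads.append((rid + f"|dup{di}", seq))
    return SimulatedLibrary(reads, n_unique, params)


def simulate_mrna_tags(genome: Genome, expression=None, n_tags: int = 100_000,
                       tag_length: int = 35, trim_margin: int = 1,
                       seed: int = 0) -> list[tuple[str, str]]:
    """Sample exact transcript substrings proportional to expression x length.

    Emitted tags are ``tag_length + trim_margin`` nt so the quantifier can
    trim the leading base, as the 35-nt (trimmed first nt) protocol does.
    """
    rng = np.random.default_rng(seed)
    if expression is None:
        expression = dict(zip(genome.genes.gene_id,
                              genome.genes.expression_oocyte))
    raw_len = tag_length + trim_margin
    tx, weights, ids = [], [], []
    for g in genome.genes.itertuples():
        t = genome.spliced_transcript(g)
        if len(t) < raw_len:
            log.info("gene %s excluded from tag simulation (exonic length "
                     "%d < %d)", g.gene_id, len(t), raw_len)
            continue
        expr = float(expression.get(g.gene_id, 0.0))
        if expr <= 0:
            continue
        tx.append(t)
        ids.append(g.gene_id)
        weights.append(expr * len(t))
    if n_tags == 0 or not tx:
        return []
    w = np.asarray(weights) / np.sum(weights)
    counts = rng.multinomial(n_tags, w)
    tags = []
    serial = 0
    for t, gid, cnt in zip(tx, ids, counts):
        if cnt == 0:
            continue
        starts = rng.integers(0, len(t) - raw_len + 1, cnt)
        for s in starts:
            tags.append((f"tag|{gid}|{serial}", t[s:s + raw_len]))
            serial += 1
    return tags


def sample_calls_from_methylome(genome: Genome, methylome: TrueMethylome,
                                depth: float = 10.0, failure_rate: float = 0.01,
                                seed: int = 0, chroms=None,
                                cpg_only: bool = False):
    """Binomially sample per-cytosine calls straight from the true methylome.

    A fast alternative to read simulation + alignment for region-level
    statistics: per-site coverage is Poisson(depth) and the C count is
    Binomial(n, m + (1-m)*eps). ``cpg_only`` restricts sampling to CpG
    cytosines when non-CpG contexts are not needed.
    """
    from .calling import CallSet

    rng = np.random.default_rng(seed)
    cs = CallSet.empty(genome)
    eps = failure_rate
    for chrom in (chroms or genome.chroms):
        e = genome.enc(chrom)
        mp, mm = methylome.levels[chrom]
        cpg = genome.cpg_starts(chrom)
        for base_code, marr, carr, tarr in (
                (1, mp, cs.c_plus[chrom], cs.t_plus[chrom]),
                (2, mm, cs.c_minus[chrom], cs.t_minus[chrom])):
            if cpg_only:
                pos = cpg if base_code == 1 else cpg + 1
            else:
                pos = np.flatnonzero(e == base_code)
            n = rng.poisson(depth, len(pos))
            pr = marr[pos] + (1.0 - marr[pos]) * eps
            c = rng.binomial(n, pr)
            carr[pos] = c
            tarr[pos] = n - c
        cs.aligned_bases[chrom] = int(round(depth * len(e)))
    return cs
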