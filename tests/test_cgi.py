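"""CGI tables, gDMR calling/classification, ICR profiling, clones."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gametemeth as gm
from gametemeth import cgi as cgm, simulate as sim


def _table(rows):
    df = pd.DataFrame(rows, columns=["oocyte", "sperm"])
    df.insert(0, "cgi_id", [f"c{i}" for i in range(len(df))])
    df.insert(1, "chrom", "chr1")
    df.insert(2, "start", np.arange(len(df)) * 1000)
    df.insert(3, "end", np.arange(len(df)) * 1000 + 500)
    return df


def test_threshold_classification_and_boundaries():
    table = _table([
        (85.0, 10.0),    # oocyte gDMR
        (80.0, 20.0),    # boundary: still a gDMR (>=80 and <=20 inclusive)
        (85.0, 25.0),    # oocyte-high only
        (10.0, 92.0),    # sperm gDMR
        (90.0, 90.0),    # both high
        (50.0, 50.0),    # neither
        (79.9, 10.0),    # below hi threshold
    ])
    sets = cgm.classify_cgi_sets(table)
    assert list(sets["oocyte_gdmr"].cgi_id) == ["c0", "c1"]
    assert list(sets["sperm_gdmr"].cgi_id) == ["c3"]
    assert list(sets["both_high"].cgi_id) == ["c4"]
    assert "c2" in set(sets["oocyte_high"].cgi_id)
    assert "c2" not in set(sets["oocyte_gdmr"].cgi_id)
    # partitions
    assert not set(sets["oocyte_gdmr"].cgi_id) & set(sets["sperm_gdmr"].cgi_id)
    assert set(sets["oocyte_gdmr"].cgi_id) <= set(sets["oocyte_high"].cgi_id)


def test_only_doubly_informative_cgis_eligible():
    table = _table([(85.0, 10.0), (85.0, np.nan)])
    sets = cgm.classify_cgi_sets(table)
    assert len(sets["informative"]) == 1
    assert list(sets["oocyte_gdmr"].cgi_id) == ["c0"]


def test_missing_sample_column_raises():
    table = _table([(85.0, 10.0)]).drop(columns=["sperm"])
    with pytest.raises(ValueError, match="missing sample column"):
        cgm.classify_cgi_sets(table)


@given(st.floats(80, 99), st.floats(1, 20))
@settings(max_examples=50, deadline=None)
def test_threshold_monotonicity(hi, lo):
    """Raising hi or lowering lo never increases gDMR counts."""
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 100, size=(300, 2))
    table = _table([tuple(v) for v in vals])
    base = cgm.classify_cgi_sets(table, cgm.DmrParams(hi=hi, lo=lo))
    tighter = cgm.classify_cgi_sets(
        table, cgm.DmrParams(hi=min(hi + 5, 100), lo=max(lo - 5, 0)))
    assert len(tighter["gdmr"]) <= len(base["gdmr"])


def test_planted_gdmr_recovery_with_noise():
    """All planted gDMRs >=5 points from thresholds are recovered; no CGI
    >=5 points outside the thresholds is called."""
    rng = np.random.default_rng(1)
    n = 5000
    classes = rng.choice(["oo", "sp", "none"], size=n, p=[0.1, 0.05, 0.85])
    oo = np.where(classes == "oo", rng.uniform(88, 99, n),
                  np.where(classes == "sp", rng.uniform(1, 12, n),
                           rng.uniform(30, 70, n)))
    sp = np.where(classes == "oo", rng.uniform(1, 12, n),
                  np.where(classes == "sp", rng.uniform(88, 99, n),
                           rng.uniform(30, 70, n)))
    noise = rng.normal(0, 3, (2, n))
    table = _table(list(zip(np.clip(oo + noise[0], 0, 100),
                            np.clip(sp + noise[1], 0, 100))))
    sets = cgm.classify_cgi_sets(table)
    true_oo = oo + noise[0]
    true_sp = sp + noise[1]
    clear_gdmr_oo = (true_oo >= 85) & (true_sp <= 15)
    clear_out = (true_oo < 75) | (true_sp > 25)
    called = np.zeros(n, bool)
    called[[int(c[1:]) for c in sets["oocyte_gdmr"].cgi_id]] = True
    assert called[clear_gdmr_oo].all()
    assert not called[clear_out].any()


def test_cgi_methylation_table_roundtrip(default_genome, oocyte_calls,
                                         sperm_calls):
    table = cgm.cgi_methylation_table(
        {"oocyte": oocyte_calls, "sperm": sperm_calls},
        default_genome.cgis, default_genome)
    assert len(table) == len(default_genome.cgis)
    merged = table.merge(default_genome.cgis[["cgi_id", "meth_class"]],
                         on="cgi_id")
    sets = cgm.classify_cgi_sets(table)
    planted_oo = set(merged[merged.meth_class == "oocyte_gdmr"].cgi_id)
    called_oo = set(sets["oocyte_gdmr"].cgi_id)
    assert called_oo == planted_oo
    planted_sp = set(merged[merged.meth_class == "sperm_gdmr"].cgi_id)
    assert set(sets["sperm_gdmr"].cgi_id) == planted_sp
    # planted ICR-like CGI recovers the maternal pattern
    if len(default_genome.icrs):
        icr_cgi = default_genome.icrs.cgi_id.iloc[0]
        row = table[table.cgi_id == icr_cgi].iloc[0]
        parent = default_genome.icrs.parent.iloc[0]
        hi, lo = (("oocyte", "sperm") if parent == "maternal"
                  else ("sperm", "oocyte"))
        assert row[hi] > 85
        assert row[lo] < 10


def test_cgi_informative_threshold(default_genome, oocyte_calls):
    """A CGI with fewer covered CpGs than the floor is non-informative."""
    from gametemeth.calling import CallSet

    empty = CallSet.empty(default_genome)
    r = default_genome.cgis.iloc[0]
    p = default_genome.cpg_starts(r.chrom)
    inside = p[(p >= r.start) & (p < r.end)][:2]   # only 2 covered CpGs
    empty.c_plus[r.chrom][inside] = 10
    table = cgm.cgi_methylation_table({"x": empty},
                                      default_genome.cgis.iloc[[0]],
                                      default_genome)
    assert not table.x_informative.iloc[0]
    assert np.isnan(table.x.iloc[0])


def test_cgi_without_reference_cpg_is_annotation_error(small_genome):
    from gametemeth.calling import CallSet

    bad = pd.DataFrame([dict(cgi_id="bad", chrom="chr1", start=0, end=1)])
    with pytest.raises(ValueError, match="no CpG"):
        cgm.cgi_methylation_table({"x": CallSet.empty(small_genome)}, bad,
                                  small_genome)


# ------------------------------------------------------------- location

def _gene(gene_id, start, end, strand, exons):
    return dict(gene_id=gene_id, chrom="chr1", start=start, end=end,
                strand=strand, exon_starts=tuple(e[0] for e in exons),
                exon_ends=tuple(e[1] for e in exons))


@pytest.fixture
def gene_models():
    return pd.DataFrame([
        _gene("gA", 10_000, 20_000, "+",
              [(10_000, 10_300), (12_000, 12_200), (14_000, 14_200),
               (16_000, 16_200), (19_700, 20_000)]),
        _gene("gB", 40_000, 50_000, "-",
              [(40_000, 40_300), (45_000, 45_200), (49_700, 50_000)]),
    ])


def _gdmr(start, end):
    return pd.DataFrame([dict(cgi_id="x", chrom="chr1", start=start,
                              end=end)])


@pytest.mark.parametrize("start,end,expected", [
    (9_600, 9_900, "promoter_or_first_exon"),    # inside 500-bp upstream
    (10_100, 10_250, "promoter_or_first_exon"),  # first exon
    (19_800, 19_900, "last_exon"),
    (14_050, 14_150, "other_exon"),
    (13_000, 13_400, "intron"),
    (30_000, 30_400, "intergenic"),
    (50_100, 50_400, "promoter_or_first_exon"),  # upstream of minus gene
    (40_100, 40_200, "last_exon"),               # 3' exon of minus gene
])
def test_gdmr_location_labels(gene_models, start, end, expected):
    lab = cgm.classify_gdmr_location(_gdmr(start, end), gene_models)
    assert lab.iloc[0] == expected


def test_location_precedence_promoter_wins(gene_models):
    # spans promoter, first exon and intron: promoter/first-exon wins
    lab = cgm.classify_gdmr_location(_gdmr(9_800, 13_000), gene_models)
    assert lab.iloc[0] == "promoter_or_first_exon"


def test_location_requires_exons(gene_models):
    broken = gene_models.copy()
    broken.at[0, "exon_starts"] = ()
    broken.at[0, "exon_ends"] = ()
    with pytest.raises(ValueError, match="without exons"):
        cgm.classify_gdmr_location(_gdmr(0, 10), broken)


# ------------------------------------------------------------- expression

def test_gdmr_expression_group(gene_models):
    expr = pd.DataFrame({"gene_id": ["gA", "gB"], "rpkm": [100.0, 1.0],
                         "group": [1, 5]})
    inside_a = _gdmr(13_000, 13_400)
    assert cgm.classify_gdmr_expression_group(
        inside_a, expr, gene_models).iloc[0] == 1
    intergenic = _gdmr(30_000, 30_200)
    assert pd.isna(cgm.classify_gdmr_expression_group(
        intergenic, expr, gene_models).iloc[0])


def test_gdmr_enrichment_in_expressed_genes_recovered(default_genome,
                                                      oocyte_calls,
                                                      sperm_calls):
    """Intragenic oocyte-gDMRs sit in genes whose oocyte methylome is
    coupled to expression; grouping uses the methylated gamete's ranking."""
    g = default_genome
    table = cgm.cgi_methylation_table(
        {"oocyte": oocyte_calls, "sperm": sperm_calls}, g.cgis, g)
    sets = cgm.classify_cgi_sets(table)
    gdmr = sets["gdmr"]
    expr = g.genes[["gene_id"]].copy()
    expr["rpkm"] = g.genes.expression_oocyte
    from gametemeth.expression import assign_expression_groups
    expr = assign_expression_groups(expr)
    groups = cgm.classify_gdmr_expression_group(gdmr, expr, g.genes)
    assert len(groups) == len(gdmr)
    assert groups.dropna().isin([1, 2, 3, 4, 5]).all()


# ------------------------------------------------------------- fate

def test_postfertilization_fate_classes():
    gdmrs = pd.DataFrame({
        "cgi_id": ["a", "b", "c", "d"],
        "gdmr_class": ["oocyte_methylated"] * 2 + ["sperm_methylated"] * 2,
        "blastocyst": [35.0, 19.9, 50.0, 5.0],
        "esc": [10.0, np.nan, 60.0, 40.0],
    })
    out = cgm.classify_postfertilization_fate(gdmrs)
    assert list(out.fate) == ["resistant", "sensitive", "resistant",
                              "sensitive"]
    assert out.esc_fate.tolist() == ["demethylated", "NA",
                                     "maintained_or_increased",
                                     "remethylated"]


def test_fate_na_without_blastocyst_value():
    gdmrs = pd.DataFrame({"cgi_id": ["a"], "blastocyst": [np.nan]})
    out = cgm.classify_postfertilization_fate(gdmrs)
    assert out.fate.iloc[0] == "NA"


# ------------------------------------------------------------- regions

def test_region_methylation_single_cpg(small_genome):
    from gametemeth.calling import CallSet

    calls = CallSet.empty(small_genome)
    p = int(small_genome.cpg_starts("chr1")[0])
    calls.c_plus["chr1"][p] = 1
    calls.t_minus["chr1"][p + 1] = 1
    iv = pd.DataFrame([dict(name="one", chrom="chr1", start=p, end=p + 2),
                       dict(name="empty", chrom="chr1", start=0, end=1)])
    out = cgm.region_methylation({"s": calls}, iv)
    assert out.s.iloc[0] == pytest.approx(50.0)
    assert np.isnan(out.s.iloc[1])


def test_region_methylation_icr_pattern(default_genome, oocyte_calls,
                                        sperm_calls):
    """Maternal ICR-like intervals: ~100% in oocyte vs ~eps in sperm."""
    icrs = default_genome.icrs
    mat = icrs[icrs.parent == "maternal"]
    out = cgm.region_methylation({"oocyte": oocyte_calls,
                                  "sperm": sperm_calls}, mat)
    assert (out.oocyte > 85).all()
    assert (out.sperm < 10).all()


def test_region_methylation_one_based_conversion(small_genome):
    from gametemeth.calling import CallSet

    calls = CallSet.empty(small_genome)
    p = int(small_genome.cpg_starts("chr1")[5])
    calls.c_plus["chr1"][p] = 4
    iv0 = pd.DataFrame([dict(name="x", chrom="chr1", start=p, end=p + 1)])
    iv1 = pd.DataFrame([dict(name="x", chrom="chr1", start=p + 1,
                             end=p + 1)])
    a = cgm.region_methylation({"s": calls}, iv0)
    b = cgm.region_methylation({"s": calls}, iv1, one_based_inclusive=True)
    assert a.s.iloc[0] == b.s.iloc[0] == 100.0


# ------------------------------------------------------------- confirmation

def test_external_confirmation_thresholds():
    gdmrs = pd.DataFrame({
        "cgi_id": ["a", "b", "c", "d"],
        "gdmr_class": ["oocyte_methylated"] * 4,
    })
    external = pd.DataFrame({
        "cgi_id": ["a", "b", "c"],
        "oocyte": [78.0, 74.0, 20.0],
        "sperm": [20.0, 20.0, 90.0],
    })
    out = cgm.confirm_gdmrs_external(gdmrs, external)
    assert list(out.cgi_id) == ["a"]       # 78/20 passes 75/25
    assert out.attrs["n_unmatched"] == 1   # 'd' absent from external


# ------------------------------------------------------------- clones

def test_allele_resolved_clone_analysis():
    poly = [(63_247_064, "G", "A"), (63_247_072, "T", "A"),
            (63_247_089, "TA", "AG")]
    clones = (
        [dict(meth=(1,) * 12 + (0,) * 4, variant_bases=("G", "T", "TA"))] * 10
        + [dict(meth=(0,) * 16, variant_bases=("A", "A", "AG"))] * 10
        + [dict(meth=(1,) * 16, variant_bases=("G", "A", "N"))]  # ambiguous
    )
    cs = cgm.CloneSet("Gpr1", clones, poly,
                      allele_names=("maternal", "paternal"))
    out = cgm.allele_resolved_clone_analysis(cs)
    assert out["ambiguous"] == 1
    assert out["maternal"]["n_clones"] == 10
    assert out["maternal"]["percent"] == pytest.approx(75.0)   # 120/160
    assert out["paternal"]["percent"] == 0.0
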