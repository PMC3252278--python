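"""Genome container and annotation/file plumbing.

A :class:`Genome` holds contig sequences plus the interval annotations the
downstream analyses need: BED12-style gene models, CpG islands (CGIs),
repeat intervals with their family label, and imprinting-control-region
(ICR)-like intervals. Coordinates are 0-based half-open throughout the
library; 1-based inclusive only at report boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pyfaidx

LAMBDA = "lambda"
NON_ANALYSIS = {"chrM", "chrY", LAMBDA}

#: repeat families removed by the alignment filter
FILTERED_REPEAT_CLASSES = ("simple_repeat", "low_complexity", "satellite")

_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T,N -> 0,1,2,3,4 as uint8."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(enc: np.ndarray) -> str:
    return _DEC[enc].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class Genome:
    """Sequences plus gene/CGI/repeat/ICR annotations.

    ``genes``   : gene_id, chrom, start, end, strand, exon_starts, exon_ends
                  (tuples of ints), expression_oocyte, expression_sperm
    ``cgis``    : cgi_id, chrom, start, end, placement, meth_class, fate, esc_fate
    ``repeats`` : chrom, start, end, family
    ``icrs``    : icr_id, chrom, start, end, parent, cgi_id
    """

    sequences: dict[str, str]
    genes: pd.DataFrame
    cgis: pd.DataFrame
    repeats: pd.DataFrame
    icrs: pd.DataFrame
    lambda_name: str | None = LAMBDA
    meta: dict = field(default_factory=dict)
    _enc_cache: dict = field(default_factory=dict, repr=False)
    _cpg_cache: dict = field(default_factory=dict, repr=False)

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    @property
    def analysis_chroms(self) -> list[str]:
        """Contigs entering genome-wide summaries (no chrM/chrY/spike-in)."""
        return [c for c in self.sequences if c not in NON_ANALYSIS]

    def enc(self, chrom: str) -> np.ndarray:
        if chrom not in self._enc_cache:
            self._enc_cache[chrom] = encode(self.sequences[chrom])
        return self._enc_cache[chrom]

    def cpg_starts(self, chrom: str) -> np.ndarray:
        """0-based positions p with sequence[p:p+2] == 'CG'."""
        if chrom not in self._cpg_cache:
            e = self.enc(chrom)
            self._cpg_cache[chrom] = np.flatnonzero((e[:-1] == 1) & (e[1:] == 2))
        return self._cpg_cache[chrom]

    def n_cpg_cytosines(self, chroms=None) -> int:
        """Count of CpG-context cytosines on both strands."""
        chroms = self.analysis_chroms if chroms is None else chroms
        return int(sum(2 * len(self.cpg_starts(c)) for c in chroms))

    def spliced_transcript(self, gene) -> str:
        """Exon-union transcript sequence, 5'->3' on the gene's strand."""
        seq = self.sequences[gene.chrom]
        body = "".join(seq[s:e] for s, e in zip(gene.exon_starts, gene.exon_ends))
        return revcomp(body) if gene.strand == "-" else body

    # -------------------------------------------------- persistence
    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "genome.fa")
        genes_to_bed12(self.genes, outdir / "genes.bed")
        _df = self.genes.copy()
        _df["exon_starts"] = _df["exon_starts"].map(lambda t: ",".join(map(str, t)))
        _df["exon_ends"] = _df["exon_ends"].map(lambda t: ",".join(map(str, t)))
        _df.to_csv(outdir / "genes.tsv", sep="\t", index=False)
        intervals_to_bed6(self.cgis, outdir / "cgis.bed", name_col="cgi_id")
        self.cgis.to_csv(outdir / "cgis.tsv", sep="\t", index=False)
        intervals_to_bed6(self.repeats, outdir / "repeats.bed", name_col="family")
        self.repeats.to_csv(outdir / "repeats.tsv", sep="\t", index=False)
        self.icrs.to_csv(outdir / "icrs.tsv", sep="\t", index=False)
        (outdir / "genome.json").write_text(
            json.dumps({"lambda_name": self.lambda_name, "meta": self.meta}, indent=1)
        )

    @classmethod
    def load(cls, indir) -> "Genome":
        indir = Path(indir)
        seqs = read_fasta(indir / "genome.fa")
        genes = pd.read_csv(indir / "genes.tsv", sep="\t")
        for col in ("exon_starts", "exon_ends"):
            genes[col] = genes[col].map(
                lambda s: tuple(int(x) for x in str(s).split(","))
            )
        cgis = pd.read_csv(indir / "cgis.tsv", sep="\t")
        repeats = pd.read_csv(indir / "repeats.tsv", sep="\t")
        icrs = pd.read_csv(indir / "icrs.tsv", sep="\t")
        info = json.loads((indir / "genome.json").read_text())
        return cls(seqs, genes, cgis, repeats, icrs,
                   lambda_name=info["lambda_name"], meta=info.get("meta", {}))


# ------------------------------------------------------------------ file I/O

def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True,
                       build_index=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def intervals_to_bed6(df: pd.DataFrame, path, name_col: str, score=0) -> None:
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["start"], "end": df["end"],
        "name": df[name_col], "score": score,
        "strand": df["strand"] if "strand" in df else ".",
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "name", "score", "strand"])
    return df


def genes_to_bed12(genes: pd.DataFrame, path) -> None:
    rows = []
    for g in genes.itertuples():
        sizes = ",".join(str(e - s) for s, e in zip(g.exon_starts, g.exon_ends))
        offs = ",".join(str(s - g.start) for s in g.exon_starts)
        rows.append((g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                     g.start, g.end, "0,0,0", len(g.exon_starts), sizes, offs))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def bed12_to_genes(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", header=None)
    rows = []
    for r in raw.itertuples(index=False):
        start = int(r[1])
        sizes = [int(x) for x in str(r[10]).rstrip(",").split(",")]
        offs = [int(x) for x in str(r[11]).rstrip(",").split(",")]
        es = tuple(start + o for o in offs)
        ee = tuple(start + o + s for o, s in zip(offs, sizes))
        rows.append(dict(gene_id=r[3], chrom=r[0], start=start, end=int(r[2]),
                         strand=r[5], exon_starts=es, exon_ends=ee))
    return pd.DataFrame(rows)


def write_fastq(reads, path) -> None:
    """Write (read_id, sequence) records with constant Phred-33 quality 'I'."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path):
    """Yield (read_id, sequence) from a FASTQ file."""
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence.upper()


def merged_intervals(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged, sorted (starts, ends) arrays for overlap queries."""
    out = {}
    for chrom, sub in df.groupby("chrom"):
        ivs = sub[["start", "end"]].sort_values("start").to_numpy()
        starts, ends = [], []
        for s, e in ivs:
            if ends and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        out[chrom] = (np.asarray(starts), np.asarray(ends))
    return out


def overlaps_any(merged: dict, chrom: str, start, end) -> np.ndarray:
    """Vectorised >=1 bp overlap test of [start,end) against merged intervals."""
    start = np.atleast_1d(np.asarray(start))
    end = np.atleast_1d(np.asarray(end))
    if chrom not in merged:
        return np.zeros(len(start), dtype=bool)
    ms, me = merged[chrom]
    if len(ms) == 0:
        return np.zeros(len(start), dtype=bool)
    idx = np.searchsorted(me, start, side="right")
    hit = (idx < len(ms)) & (ms[np.minimum(idx, len(ms) - 1)] < end)
    return hit
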