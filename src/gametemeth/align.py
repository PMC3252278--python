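"""Three-letter conversion alignment of bisulfite reads.

The reference is held as two converted texts: the forward strand with C
replaced by T ("CT" space) and the forward strand with G replaced by A
("GA" space, which is the reverse complement image of the converted bottom
strand). A read is searched, after its own conversion, in up to four
(read-conversion, reference-text) combinations; each verified full-length,
mismatch-free placement is one hit:

====  ===========================  =========  ======
bs    query                        text       strand
====  ===========================  =========  ======
OT    C->T(read)                   CT         ``+``
OB    revcomp(C->T(read))          GA         ``-``
CTOB  G->A(read)                   GA         ``+``
CTOT  revcomp(G->A(read))          CT         ``-``
====  ===========================  =========  ======

Directional MethylC-seq libraries search OT/OB; amplified WBA libraries
search all four; PBAT libraries, whose reads are complements of converted
strands, search CTOT/CTOB. A read is usable downstream only when exactly
one placement exists across all searched combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (FILTERED_REPEAT_CLASSES, Genome, encode, merged_intervals,
                     overlaps_any, revcomp)

MIN_TAG_LENGTH = 32

_CT = str.maketrans("Cc", "Tt")
_GA = str.maketrans("Gg", "Aa")

_IUPAC_OK = frozenset("ACGTN")


def convert_sequence(seq: str, mode: str) -> str:
    """Replace C->T (``c_to_t``) or G->A (``g_to_a``), length-preserving."""
    bad = set(seq.upper()) - _IUPAC_OK
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    if mode == "c_to_t":
        return seq.translate(_CT)
    if mode == "g_to_a":
        return seq.translate(_GA)
    raise ValueError(f"unknown conversion mode {mode!r}")


_POW = (np.uint64(4) ** np.arange(31, -1, -1, dtype=np.uint64))


class ExactIndex:
    """Exact-match substring index: sorted 32-mer codes + verification.

    Queries must be at least 32 nt; the leading 32-mer is looked up in the
    sorted code array and every candidate is verified by direct string
    comparison, so results equal a naive scan.
    """

    K = 32

    def __init__(self, text: str):
        self.text = text
        enc = encode(text)
        n = len(enc)
        if n < self.K:
            self.sorted_codes = np.empty(0, np.uint64)
            self.positions = np.empty(0, np.int64)
            return
        m = n - self.K + 1
        codes = np.zeros(m, dtype=np.uint64)
        e64 = enc.astype(np.uint64)
        for i in range(self.K):
            codes = codes * np.uint64(4) + e64[i:i + m]
        # windows containing N are invalid
        isn = (enc == 4).astype(np.int64)
        cum = np.concatenate([[0], np.cumsum(isn)])
        valid = (cum[self.K:] - cum[:-self.K]) == 0
        pos = np.flatnonzero(valid)
        codes = codes[pos]
        order = np.argsort(codes, kind="stable")
        self.sorted_codes = codes[order]
        self.positions = pos[order].astype(np.int64)

    def _code(self, seq32: str) -> int | None:
        e = encode(seq32)
        if (e == 4).any():
            return None
        return int(np.dot(e.astype(np.uint64), _POW))

    def find(self, seq: str) -> list[int]:
        """All positions where ``seq`` occurs exactly (full length)."""
        if len(seq) < self.K:
            raise ValueError(f"query shorter than {self.K} nt")
        code = self._code(seq[:self.K])
        if code is None:
            return []
        code = np.uint64(code)
        lo = int(np.searchsorted(self.sorted_codes, code, side="left"))
        hi = int(np.searchsorted(self.sorted_codes, code, side="right"))
        out = []
        text = self.text
        for p in self.positions[lo:hi]:
            p = int(p)
            if text[p:p + len(seq)] == seq:
                out.append(p)
        return sorted(out)


@dataclass
class ConvertedReference:
    """Index over both converted images of a genome."""

    chrom_names: list[str]
    chrom_starts: np.ndarray      # global offset of each contig
    chrom_lengths: np.ndarray
    index_ct: ExactIndex
    index_ga: ExactIndex

    def locate(self, global_pos: int, length: int):
        """Map a global text position to (chrom, local_start); None if the
        match would straddle a contig boundary."""
        i = int(np.searchsorted(self.chrom_starts, global_pos, side="right")) - 1
        local = global_pos - int(self.chrom_starts[i])
        if local + length > int(self.chrom_lengths[i]):
            return None
        return self.chrom_names[i], local


def build_reference_index(genome) -> ConvertedReference:
    """Build CT- and GA-space exact-match indexes over all contigs.

    ``genome`` may be a :class:`Genome` or a plain {name: sequence} dict.
    """
    sequences = genome.sequences if isinstance(genome, Genome) else genome
    if not sequences or all(len(s) == 0 for s in sequences.values()):
        raise ValueError("empty genome")
    names = list(sequences)
    lengths = np.array([len(sequences[c]) for c in names], dtype=np.int64)
    # contigs joined by N so no 32-mer can span a boundary
    joined = "N".join(sequences[c].upper() for c in names)
    starts = np.concatenate([[0], np.cumsum(lengths[:-1] + 1)])
    return ConvertedReference(
        chrom_names=names, chrom_starts=starts, chrom_lengths=lengths,
        index_ct=ExactIndex(joined.translate(_CT)),
        index_ga=ExactIndex(joined.translate(_GA)),
    )


#: bs_strand -> (which text, query builder, strand symbol)
_SEARCHES = {
    "OT": ("ct", lambda r: r.translate(_CT), "+"),
    "OB": ("ga", lambda r: revcomp(r.translate(_CT)), "-"),
    "CTOB": ("ga", lambda r: r.translate(_GA), "+"),
    "CTOT": ("ct", lambda r: revcomp(r.translate(_GA)), "-"),
}

PROTOCOL_SEARCHES = {"methylc": ("OT", "OB"),
                     "wba": ("OT", "OB", "CTOT", "CTOB"),
                     "pbat": ("CTOT", "CTOB")}

ALIGNMENT_COLUMNS = ["read_id", "chrom", "start", "strand", "bisulfite_strand",
                     "length", "n_hits", "seq"]


def align_reads(reads, index: ConvertedReference, protocol: str = "methylc",
                trim: tuple[int, int] = (0, 0)) -> pd.DataFrame:
    """Exact-match align reads; one row per read that hit at least once.

    ``reads`` is an iterable of (read_id, sequence) pairs (or a
    :class:`~gametemeth.simulate.SimulatedLibrary`). Reads shorter than 32 nt
    after trimming are skipped (counted in ``df.attrs['n_too_short']``).
    Ambiguous reads are emitted with their ``n_hits`` for the filter stage.
    """
    if protocol not in PROTOCOL_SEARCHES:
        raise ValueError(f"unknown protocol {protocol!r}")
    if hasattr(reads, "reads"):
        reads = reads.reads
    head, tail = trim
    searches = PROTOCOL_SEARCHES[protocol]
    rows = []
    n_too_short = 0
    texts = {"ct": index.index_ct, "ga": index.index_ga}
    for rid, seq in reads:
        seq = seq.upper()
        if tail:
            seq = seq[head:-tail]
        elif head:
            seq = seq[head:]
        L = len(seq)
        if L < MIN_TAG_LENGTH:
            n_too_short += 1
            continue
        hits = []
        for bs in searches:
            text_key, make_query, strand = _SEARCHES[bs]
            q = make_query(seq)
            for gp in texts[text_key].find(q):
                loc = index.locate(gp, L)
                if loc is not None:
                    hits.append((loc[0], loc[1], strand, bs))
        if not hits:
            continue
        chrom, start, strand, bs = hits[0]
        rows.append((rid, chrom, start, strand, bs, L, len(hits), seq))
    df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    df.attrs["n_too_short"] = n_too_short
    df.attrs["protocol"] = protocol
    return df


@dataclass
class FilteredAlignments:
    """Main analysis stream plus the separately-examined mitochondrial one."""

    main: pd.DataFrame
    mito: pd.DataFrame
    counters: dict = field(default_factory=dict)


def filter_alignments(alignments: pd.DataFrame, genome: Genome | None = None,
                      repeats: pd.DataFrame | None = None,
                      drop_repeat_classes=FILTERED_REPEAT_CLASSES,
                      require_repeats: bool = True) -> FilteredAlignments:
    """Apply the mapping filters.

    Drops multi-hit tags, chrY, and tags overlapping (>=1 bp) simple repeat,
    low complexity, or satellite intervals; chrM tags are diverted to a
    separate stream rather than discarded.
    """
    if repeats is None:
        if genome is not None:
            repeats = genome.repeats
        elif require_repeats:
            raise ValueError("repeat annotation required: pass genome= or "
                             "repeats=, or set require_repeats=False")
        else:
            repeats = pd.DataFrame(columns=["chrom", "start", "end", "family"])
    counters = {"input": len(alignments)}
    df = alignments[alignments.n_hits == 1]
    counters["multi_hit"] = counters["input"] - len(df)
    mito = df[df.chrom == "chrM"].reset_index(drop=True)
    df = df[df.chrom != "chrM"]
    n = len(df)
    df = df[df.chrom != "chrY"]
    counters["chrY"] = n - len(df)
    counters["chrM_diverted"] = len(mito)
    merged = merged_intervals(
        repeats[repeats.family.isin(drop_repeat_classes)])
    keep_parts = []
    n_repeat = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        bad = overlaps_any(merged, chrom, sub.start.to_numpy(),
                           (sub.start + sub.length).to_numpy())
        n_repeat += int(bad.sum())
        keep_parts.append(sub[~bad])
    counters["repeat_overlap"] = n_repeat
    main = (pd.concat(keep_parts).reset_index(drop=True) if keep_parts
            else df.iloc[0:0].reset_index(drop=True))
    counters["kept"] = len(main)
    return FilteredAlignments(main=main, mito=mito, counters=counters)


def deduplicate_alignments(alignments: pd.DataFrame) -> pd.DataFrame:
    """Keep the first alignment per (chrom, start, bisulfite_strand)."""
    return alignments.drop_duplicates(
        subset=["chrom", "start", "bisulfite_strand"],
        keep="first").reset_index(drop=True)
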