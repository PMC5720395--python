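"""Coding gene models, substitution-class indexing and site-composition matrices.

Somatic dN/dS models classify every possible coding substitution by its
substitution class *i* (the ref>alt change plus up to two bases of flanking
context, indexed on the coding strand of each gene) and by its functional
impact *c*: synonymous (s), missense (m), nonsense (n) or essential splice
site (e).  The composition matrix ``L[i, c]`` counts, for one gene, the number
of sites at which a substitution of class *i* has impact *c*.  These matrices
are the exposure terms of every Poisson selection model in this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
IMPACTS = ("s", "m", "n", "e")
IMPACT_INDEX = {c: i for i, c in enumerate(IMPACTS)}

# Default essential-splice definition: intronic offsets relative to each
# exon/intron boundary, in transcript direction.
DONOR_OFFSETS = (1, 2, 5)
ACCEPTOR_OFFSETS = (1, 2)

MAX_CONTEXT_WIDTH = 2

# --- standard genetic code as a 64-entry lookup (codon id = 16*b0+4*b1+b2) ---


def _codon_table() -> np.ndarray:
    table = CodonTable.unambiguous_dna_by_id[1]
    aa = np.empty(64, dtype="<U1")
    for i0, b0 in enumerate(BASES):
        for i1, b1 in enumerate(BASES):
            for i2, b2 in enumerate(BASES):
                codon = b0 + b1 + b2
                idx = 16 * i0 + 4 * i1 + i2
                aa[idx] = "*" if codon in table.stop_codons else table.forward_table[codon]
    return aa


CODON_AA = _codon_table()

# OTHER_BASES[ref, rank] = the rank-th alternative base index (rank 0..2)
OTHER_BASES = np.array([[j for j in range(4) if j != i] for i in range(4)], dtype=np.int8)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class SubstitutionClassIndex:
    """Bijective mapping (context, ref, alt) -> class id on the coding strand.

    ``context_width`` w gives 12 * 4**(2w) classes: 12 base changes times all
    combinations of w upstream and w downstream bases.  w=1 is the full
    trinucleotide model (192 classes, strand-asymmetric); w=2 the
    pentanucleotide model (3,072 classes); w=0 the context-free 12-rate model.
    """

    def __init__(self, context_width: int = 1):
        if context_width not in (0, 1, 2):
            raise ValueError("context_width must be 0, 1 or 2")
        self.context_width = context_width
        self.class_count = 12 * 4 ** (2 * context_width)

    def class_id(self, upstream: str, ref: str, alt: str, downstream: str) -> int:
        w = self.context_width
        if ref == alt:
            raise ValueError("ref and alt must differ")
        ri = BASE_INDEX[ref]
        ai = BASE_INDEX[alt]
        rank = ai if ai < ri else ai - 1
        pair = ri * 3 + rank
        up = upstream[len(upstream) - w:] if w else ""
        down = downstream[:w]
        if len(up) < w or len(down) < w:
            raise ValueError("context shorter than required width")
        code = pair
        for b in up:
            code = code * 4 + BASE_INDEX[b]
        for b in down:
            code = code * 4 + BASE_INDEX[b]
        return code

    def class_ids(self, up_codes: np.ndarray, ref_idx: np.ndarray,
                  alt_rank: np.ndarray, down_codes: np.ndarray) -> np.ndarray:
        """Vectorized class ids from pre-encoded base-4 context codes."""
        w = self.context_width
        pair = ref_idx.astype(np.int64) * 3 + alt_rank
        return (pair * 4 ** w + up_codes) * 4 ** w + down_codes

    def label(self, class_id: int) -> str:
        w = self.context_width
        down = ""
        up = ""
        code = class_id
        for _ in range(w):
            down = BASES[code % 4] + down
            code //= 4
        for _ in range(w):
            up = BASES[code % 4] + up
            code //= 4
        pair = code
        ri, rank = divmod(pair, 3)
        ref = BASES[ri]
        alt = BASES[OTHER_BASES[ri, rank]]
        return f"{up}[{ref}>{alt}]{down}"


class GeneModelError(ValueError):
    pass


@dataclass
class CodingGene:
    """A single canonical CDS with genomic bookkeeping and flanking context.

    ``cds_sequence`` is on the coding strand, in transcript order, length
    divisible by 3.  ``genomic_positions[k]`` is the 1-based genomic
    coordinate of CDS base k.  ``context_windows[k]`` holds the coding-strand
    genomic context of CDS base k as base indices over a (2*MAX_CONTEXT_WIDTH+1)
    window centred on the base (intronic/flanking bases included, so contexts
    at exon boundaries are genomic, not spliced).
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_intervals: list[tuple[int, int]]
    cds_sequence: str
    genomic_positions: np.ndarray
    context_windows: np.ndarray
    splice_positions: list[int] = field(default_factory=list)
    splice_windows: np.ndarray | None = None
    flank_5p: str = ""
    flank_3p: str = ""

    def __post_init__(self):
        if len(self.cds_sequence) % 3 != 0:
            raise GeneModelError(f"{self.gene_id}: CDS length {len(self.cds_sequence)} not divisible by 3")
        if set(self.cds_sequence) - set(BASES):
            raise GeneModelError(f"{self.gene_id}: non-ACGT bases in CDS")

    @property
    def cds_length(self) -> int:
        return len(self.cds_sequence)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    def protein(self) -> str:
        idx = np.array([BASE_INDEX[b] for b in self.cds_sequence], dtype=np.int8)
        codons = idx.reshape(-1, 3)
        cid = 16 * codons[:, 0] + 4 * codons[:, 1] + codons[:, 2]
        return "".join(CODON_AA[cid])

    def cds_index_of(self, position: int) -> int | None:
        """Transcript (0-based) index of a genomic position, or None."""
        if not hasattr(self, "_pos_lookup"):
            self._pos_lookup = {int(p): k for k, p in enumerate(self.genomic_positions)}
        return self._pos_lookup.get(position)

    def is_splice_position(self, position: int) -> bool:
        return position in set(self.splice_positions)


@dataclass
class ImpactAnnotation:
    gene_id: str
    class_id: int
    impact: str
    codon_index: int | None = None
    aa_change: str | None = None


@dataclass
class CompositionMatrix:
    gene_id: str
    L: np.ndarray  # class_count x 4 (s, m, n, e)
    context_width: int

    def total_sites(self) -> int:
        return int(self.L.sum())


class AnnotationError(ValueError):
    pass


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _windows_from_chromosome(chrom_idx: np.ndarray, positions: np.ndarray, strand: str,
                             gene_id: str) -> np.ndarray:
    """(n, 5) coding-strand context windows around 1-based genomic positions."""
    w = MAX_CONTEXT_WIDTH
    offs = np.arange(-w, w + 1)
    idx0 = positions[:, None] - 1 + offs[None, :]
    if idx0.size and (idx0.min() < 0 or idx0.max() >= len(chrom_idx)):
        raise GeneModelError(
            f"{gene_id}: requires {w} flanking bases around every coding/splice position")
    win = chrom_idx[idx0]
    if (win < 0).any():
        raise GeneModelError(f"{gene_id}: ambiguous (non-ACGT) base inside a context window")
    if strand == "-":
        win = 3 - win[:, ::-1]
    return win.astype(np.int8)


def gene_from_reference(gene_id: str, chromosome: str, strand: str,
                        cds_intervals: list[tuple[int, int]],
                        chrom_seq: str,
                        chrom_idx: np.ndarray | None = None,
                        splice_rule: tuple = (DONOR_OFFSETS, ACCEPTOR_OFFSETS)) -> CodingGene:
    """Assemble a validated CodingGene from a reference chromosome sequence.

    ``cds_intervals`` are 1-based inclusive genomic intervals given in
    transcript (5'->3') order; for '-' strand genes this means decreasing
    genomic coordinates.
    """
    if strand not in "+-":
        raise GeneModelError(f"{gene_id}: strand must be + or -")
    if chrom_idx is None:
        chrom_idx = _encode(chrom_seq)
    step = 1 if strand == "+" else -1
    pos_list = []
    for (a, b) in cds_intervals:
        if a > b:
            raise GeneModelError(f"{gene_id}: interval start > end ({a} > {b})")
        span = np.arange(a, b + 1) if strand == "+" else np.arange(b, a - 1, -1)
        pos_list.append(span)
    positions = np.concatenate(pos_list)
    if len(set(positions.tolist())) != len(positions):
        raise GeneModelError(f"{gene_id}: overlapping CDS intervals")
    windows = _windows_from_chromosome(chrom_idx, positions, strand, gene_id)
    cds_idx = windows[:, MAX_CONTEXT_WIDTH]
    cds_sequence = "".join(BASES[i] for i in cds_idx)
    if len(cds_sequence) % 3 != 0:
        raise GeneModelError(f"{gene_id}: CDS length {len(cds_sequence)} not divisible by 3")
    aa = CODON_AA[(cds_idx.reshape(-1, 3) * np.array([16, 4, 1])).sum(axis=1)]
    if "*" in aa[:-1]:
        stops = np.nonzero(aa[:-1] == "*")[0]
        raise GeneModelError(f"{gene_id}: internal stop codon at codon {int(stops[0]) + 1}")

    donor_offsets, acceptor_offsets = splice_rule
    splice_positions: list[int] = []
    for k in range(len(cds_intervals) - 1):
        a0, b0 = cds_intervals[k]
        a1, b1 = cds_intervals[k + 1]
        donor_boundary = b0 if strand == "+" else a0    # last transcript base of exon k
        acceptor_boundary = a1 if strand == "+" else b1  # first transcript base of exon k+1
        for off in donor_offsets:
            splice_positions.append(donor_boundary + step * off)
        for off in acceptor_offsets:
            splice_positions.append(acceptor_boundary - step * off)
    splice_positions = sorted(set(splice_positions) - set(positions.tolist()))
    splice_windows = (_windows_from_chromosome(chrom_idx, np.array(splice_positions, dtype=int),
                                               strand, gene_id)
                      if splice_positions else np.empty((0, 2 * MAX_CONTEXT_WIDTH + 1), dtype=np.int8))

    w = MAX_CONTEXT_WIDTH
    first, last = int(positions[0]), int(positions[-1])
    if strand == "+":
        flank5 = chrom_seq[first - 1 - w:first - 1]
        flank3 = chrom_seq[last:last + w]
    else:
        flank5 = reverse_complement(chrom_seq[first:first + w])
        flank3 = reverse_complement(chrom_seq[last - 1 - w:last - 1])

    return CodingGene(
        gene_id=gene_id, chromosome=chromosome, strand=strand,
        cds_intervals=list(cds_intervals), cds_sequence=cds_sequence,
        genomic_positions=positions, context_windows=windows,
        splice_positions=splice_positions, splice_windows=splice_windows,
        flank_5p=flank5, flank_3p=flank3,
    )


def read_gene_table(path) -> "pd.DataFrame":
    import pandas as pd
    tbl = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "chromosome", "strand", "cds_starts", "cds_ends"}
    missing = required - set(tbl.columns)
    if missing:
        raise GeneModelError(f"gene table missing columns: {sorted(missing)}")
    return tbl


def build_gene_model(reference, gene_table, splice_rule=(DONOR_OFFSETS, ACCEPTOR_OFFSETS)):
    """Build validated CodingGene records from FASTA + gene table.

    Parameters
    ----------
    reference : path to a FASTA file, or dict {chromosome: sequence string}.
    gene_table : path to a TSV with columns gene_id, chromosome, strand,
        cds_starts, cds_ends (comma-separated 1-based inclusive coordinates in
        transcript order), or an equivalent pandas DataFrame.

    Returns
    -------
    (genes, skipped) where ``skipped`` is a list of (gene_id, reason) for
    genes failing validation.
    """
    import pandas as pd
    if isinstance(reference, (str,)) or hasattr(reference, "read"):
        chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(reference, "fasta")}
    else:
        chroms = {k: v.upper() for k, v in reference.items()}
    encoded = {k: _encode(v) for k, v in chroms.items()}
    tbl = gene_table if isinstance(gene_table, pd.DataFrame) else read_gene_table(gene_table)

    genes: list[CodingGene] = []
    skipped: list[tuple[str, str]] = []
    for row in tbl.itertuples(index=False):
        gid = str(row.gene_id)
        try:
            chrom = str(row.chromosome)
            if chrom not in chroms:
                raise GeneModelError(f"{gid}: unknown chromosome {chrom!r}")
            starts = [int(x) for x in str(row.cds_starts).split(",")]
            ends = [int(x) for x in str(row.cds_ends).split(",")]
            if len(starts) != len(ends):
                raise GeneModelError(f"{gid}: cds_starts/cds_ends length mismatch")
            gene = gene_from_reference(gid, chrom, str(row.strand),
                                       list(zip(starts, ends)), chroms[chrom],
                                       chrom_idx=encoded[chrom], splice_rule=splice_rule)
            genes.append(gene)
        except GeneModelError as exc:
            skipped.append((gid, str(exc)))
    return genes, skipped


GENE_MODEL_CACHE_VERSION = 1


def save_gene_model(genes: list[CodingGene], path) -> None:
    """Serialize built gene models to a versioned JSON cache."""
    import json
    payload = {"version": GENE_MODEL_CACHE_VERSION, "genes": []}
    for g in genes:
        payload["genes"].append({
            "gene_id": g.gene_id, "chromosome": g.chromosome, "strand": g.strand,
            "cds_intervals": [list(iv) for iv in g.cds_intervals],
            "cds_sequence": g.cds_sequence,
            "genomic_positions": g.genomic_positions.tolist(),
            "context_windows": g.context_windows.tolist(),
            "splice_positions": list(g.splice_positions),
            "splice_windows": (g.splice_windows.tolist()
                               if g.splice_windows is not None else []),
            "flank_5p": g.flank_5p, "flank_3p": g.flank_3p,
        })
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_gene_model(path) -> list[CodingGene]:
    import json
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("version") != GENE_MODEL_CACHE_VERSION:
        raise GeneModelError(
            f"unsupported gene-model cache version {payload.get('version')!r}")
    genes = []
    for d in payload["genes"]:
        genes.append(CodingGene(
            gene_id=d["gene_id"], chromosome=d["chromosome"], strand=d["strand"],
            cds_intervals=[tuple(iv) for iv in d["cds_intervals"]],
            cds_sequence=d["cds_sequence"],
            genomic_positions=np.array(d["genomic_positions"], dtype=int),
            context_windows=np.array(d["context_windows"], dtype=np.int8),
            splice_positions=list(d["splice_positions"]),
            splice_windows=np.array(d["splice_windows"], dtype=np.int8).reshape(
                len(d["splice_positions"]), -1) if d["splice_windows"]
            else np.empty((0, 2 * MAX_CONTEXT_WIDTH + 1), dtype=np.int8),
            flank_5p=d["flank_5p"], flank_3p=d["flank_3p"]))
    return genes


# --- site enumeration and composition -------------------------------------


def site_enumeration(gene: CodingGene, index: SubstitutionClassIndex) -> dict:
    """Enumerate every possible substitution in the gene (coding + splice).

    Returns arrays of equal length (3 per site): genomic position, coding-strand
    ref/alt base indices, substitution class id, impact index, and transcript
    CDS index (-1 for splice sites).  This single enumeration backs both the
    composition matrix and the neutral simulators.
    """
    w = index.context_width
    mw = MAX_CONTEXT_WIDTH
    win = gene.context_windows
    n = gene.cds_length
    ref = win[:, mw].astype(np.int64)
    if w:
        up = np.zeros(n, dtype=np.int64)
        down = np.zeros(n, dtype=np.int64)
        for k in range(w):
            up = up * 4 + win[:, mw - w + k]
            down = down * 4 + win[:, mw + 1 + k]
    else:
        up = down = np.zeros(n, dtype=np.int64)

    codons = ref.reshape(-1, 3)
    codon_id = codons @ np.array([16, 4, 1])
    aa_ref = CODON_AA[codon_id]
    pos_in_codon = np.tile(np.array([0, 1, 2]), n // 3)
    codon_of_site = np.repeat(np.arange(n // 3), 3)
    place = np.array([16, 4, 1])[pos_in_codon]

    parts = []
    for rank in range(3):
        alt = OTHER_BASES[ref, rank].astype(np.int64)
        alt_codon_id = codon_id[codon_of_site] + (alt - ref) * place
        aa_alt = CODON_AA[alt_codon_id]
        ref_aa = aa_ref[codon_of_site]
        impact = np.where(aa_alt == ref_aa, 0,
                          np.where((aa_alt == "*") | (ref_aa == "*"), 2, 1))
        cls = index.class_ids(up, ref, np.full(n, rank), down)
        parts.append((gene.genomic_positions, ref, alt, cls, impact,
                      np.arange(n)))

    sw = gene.splice_windows
    if sw is not None and len(sw):
        m = len(sw)
        sref = sw[:, mw].astype(np.int64)
        if w:
            sup = np.zeros(m, dtype=np.int64)
            sdown = np.zeros(m, dtype=np.int64)
            for k in range(w):
                sup = sup * 4 + sw[:, mw - w + k]
                sdown = sdown * 4 + sw[:, mw + 1 + k]
        else:
            sup = sdown = np.zeros(m, dtype=np.int64)
        spos = np.array(gene.splice_positions, dtype=int)
        for rank in range(3):
            alt = OTHER_BASES[sref, rank].astype(np.int64)
            cls = index.class_ids(sup, sref, np.full(m, rank), sdown)
            parts.append((spos, sref, alt, cls, np.full(m, 3), np.full(m, -1)))

    return {
        "position": np.concatenate([p[0] for p in parts]),
        "ref": np.concatenate([p[1] for p in parts]).astype(np.int8),
        "alt": np.concatenate([p[2] for p in parts]).astype(np.int8),
        "class_id": np.concatenate([p[3] for p in parts]),
        "impact": np.concatenate([p[4] for p in parts]).astype(np.int8),
        "cds_index": np.concatenate([p[5] for p in parts]),
    }


def composition_matrix(gene: CodingGene, index: SubstitutionClassIndex) -> CompositionMatrix:
    """Count sites per (substitution class, impact): the exposure matrix L."""
    sites = site_enumeration(gene, index)
    L = np.zeros((index.class_count, 4), dtype=np.int64)
    np.add.at(L, (sites["class_id"], sites["impact"].astype(int)), 1)
    return CompositionMatrix(gene_id=gene.gene_id, L=L, context_width=index.context_width)


def annotate_substitution(gene: CodingGene, position: int, ref: str, alt: str,
                          index: SubstitutionClassIndex) -> ImpactAnnotation:
    """Classify one genomic substitution against a gene.

    ``ref``/``alt`` are on the genomic (+) strand; for '-' strand genes they
    are complemented onto the coding strand before classification, so rate
    classes capture transcriptional strand asymmetry.
    """
    w = index.context_width
    mw = MAX_CONTEXT_WIDTH
    if ref not in BASE_INDEX or alt not in BASE_INDEX or ref == alt:
        raise AnnotationError(f"invalid substitution {ref}>{alt}")
    ref_i = BASE_INDEX[ref]
    alt_i = BASE_INDEX[alt]
    if gene.strand == "-":
        ref_i, alt_i = 3 - ref_i, 3 - alt_i

    k = gene.cds_index_of(position)
    if k is not None:
        win = gene.context_windows[k]
        if win[mw] != ref_i:
            raise AnnotationError(
                f"{gene.gene_id}: reference mismatch at {gene.chromosome}:{position} "
                f"(expected {BASES[win[mw]]} on coding strand, got {BASES[ref_i]})")
        up = "".join(BASES[i] for i in win[mw - w:mw]) if w else ""
        down = "".join(BASES[i] for i in win[mw + 1:mw + 1 + w]) if w else ""
        cls = index.class_id(up, BASES[ref_i], BASES[alt_i], down)
        codon_idx = k // 3
        codon = gene.cds_sequence[3 * codon_idx:3 * codon_idx + 3]
        aa_ref = CODON_AA[16 * BASE_INDEX[codon[0]] + 4 * BASE_INDEX[codon[1]] + BASE_INDEX[codon[2]]]
        alt_codon = list(codon)
        alt_codon[k % 3] = BASES[alt_i]
        aa_alt = CODON_AA[sum(BASE_INDEX[b] * m for b, m in zip(alt_codon, (16, 4, 1)))]
        if aa_alt == aa_ref:
            impact = "s"
        elif aa_alt == "*" or aa_ref == "*":
            impact = "n"
        else:
            impact = "m"
        return ImpactAnnotation(gene_id=gene.gene_id, class_id=cls, impact=impact,
                                codon_index=codon_idx, aa_change=f"{aa_ref}>{aa_alt}")

    try:
        j = gene.splice_positions.index(position)
    except ValueError:
        raise AnnotationError(f"{gene.gene_id}: position {gene.chromosome}:{position} "
                              "not in CDS or essential-splice set") from None
    win = gene.splice_windows[j]
    if win[mw] != ref_i:
        raise AnnotationError(
            f"{gene.gene_id}: reference mismatch at splice site {gene.chromosome}:{position}")
    up = "".join(BASES[i] for i in win[mw - w:mw]) if w else ""
    down = "".join(BASES[i] for i in win[mw + 1:mw + 1 + w]) if w else ""
    cls = index.class_id(up, BASES[ref_i], BASES[alt_i], down)
    return ImpactAnnotation(gene_id=gene.gene_id, class_id=cls, impact="e",
                            codon_index=None, aa_change="splice")
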