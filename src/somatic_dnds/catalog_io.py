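"""Somatic mutation catalogs: reading, validation, cohort filters, per-gene counts.

The canonical input is a 5-column table (sampleID, chr, pos, ref, alt) of
somatic substitutions and indels, one row per mutation per sample.  Counting
routes substitutions through the coding-strand impact annotator and assigns
indels to the gene whose CDS (or essential-splice set) contains their leftmost
affected base.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_model import (AnnotationError, BASES, CodingGene, IMPACT_INDEX,
                           SubstitutionClassIndex, annotate_substitution)

CATALOG_COLUMNS = ["sampleID", "chr", "pos", "ref", "alt"]


@dataclass(frozen=True)
class MutationRecord:
    sample_id: str
    chromosome: str
    position: int  # 1-based, leftmost affected base
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        return "substitution" if len(self.ref) == 1 == len(self.alt) else "indel"


@dataclass
class CatalogReport:
    n_read: int = 0
    n_valid: int = 0
    rejected: list = field(default_factory=list)  # (line_number, reason)


class CatalogError(ValueError):
    pass


def read_catalog(path, max_error_fraction: float = 0.05):
    """Read a 5-column TSV catalog; collect malformed lines.

    Aborts only if the fraction of malformed records exceeds
    ``max_error_fraction``.  Returns (records, CatalogReport).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:5]) != CATALOG_COLUMNS:
        # headerless files are accepted if they have exactly 5 columns
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        if df.shape[1] != 5:
            raise CatalogError(
                f"expected columns {CATALOG_COLUMNS}, got {list(df.columns)}")
        df.columns = CATALOG_COLUMNS
    report = CatalogReport(n_read=len(df))
    records = []
    valid_bases = set(BASES)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ref = str(row.ref).upper()
        alt = str(row.alt).upper()
        try:
            pos = int(row.pos)
        except (TypeError, ValueError):
            report.rejected.append((i, f"non-integer position {row.pos!r}"))
            continue
        if not ref or not alt or (set(ref) | set(alt)) - valid_bases:
            report.rejected.append((i, f"non-ACGT alleles {ref}>{alt}"))
            continue
        if ref == alt:
            report.rejected.append((i, f"ref equals alt ({ref})"))
            continue
        records.append(MutationRecord(str(row.sampleID), str(row.chr), pos, ref, alt))
    report.n_valid = len(records)
    if report.n_read and len(report.rejected) / report.n_read > max_error_fraction:
        raise CatalogError(
            f"{len(report.rejected)}/{report.n_read} malformed records "
            f"exceeds the tolerated fraction {max_error_fraction}")
    return records, report


def write_catalog(records, path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.chromosome, r.position, r.ref, r.alt) for r in records],
        columns=CATALOG_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_vcf_catalog(path, sample_id: str = "sample"):
    """Minimal single-sample VCF subset reader (CHROM/POS/REF/ALT)."""
    records = []
    report = CatalogReport()
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            report.n_read += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                report.rejected.append((i, "fewer than 5 VCF columns"))
                continue
            chrom, pos, _, ref, alts = fields[:5]
            for alt in alts.split(","):
                if (set(ref) | set(alt)) - set(BASES):
                    report.rejected.append((i, f"non-ACGT alleles {ref}>{alt}"))
                    continue
                records.append(MutationRecord(sample_id, chrom, int(pos), ref.upper(), alt.upper()))
    report.n_valid = len(records)
    return records, report


# --- gene lookup across a genome ------------------------------------------


class GenomeIndex:
    """Position -> gene lookup with the deterministic overlap rule.

    When genes overlap, a position is attributed to the gene with the longest
    CDS, ties broken by lexicographic gene id.
    """

    def __init__(self, genes: list[CodingGene]):
        self.genes = {g.gene_id: g for g in genes}
        self._lookup: dict[tuple[str, int], str] = {}
        priority = sorted(genes, key=lambda g: (-g.cds_length, g.gene_id), reverse=True)
        # lowest priority first so highest priority overwrites
        for g in priority:
            for p in g.genomic_positions:
                self._lookup[(g.chromosome, int(p))] = g.gene_id
            for p in g.splice_positions:
                self._lookup[(g.chromosome, int(p))] = g.gene_id

    def gene_at(self, chromosome: str, position: int) -> CodingGene | None:
        gid = self._lookup.get((chromosome, position))
        return self.genes[gid] if gid else None


@dataclass
class CohortSummary:
    per_sample_coding: dict
    excluded_samples: dict  # sample -> reason
    n_duplicates_removed: int = 0


def filter_cohort(records, max_coding_per_sample: float = float("inf"),
                  deduplicate: bool = True, genome_index: GenomeIndex | None = None):
    """Apply cohort-level sample filters.

    Samples whose coding mutation count (substitutions and indels) exceeds
    ``max_coding_per_sample`` are removed; exact duplicate records are
    collapsed.  If no ``genome_index`` is supplied every record counts as
    coding.
    """
    n_dup = 0
    if deduplicate:
        seen = set()
        unique = []
        for r in records:
            key = (r.sample_id, r.chromosome, r.position, r.ref, r.alt)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            unique.append(r)
        records = unique

    counts: Counter = Counter()
    for r in records:
        if genome_index is None or genome_index.gene_at(r.chromosome, r.position) is not None:
            counts[r.sample_id] += 1
    excluded = {s: f"{c} coding mutations > cap {max_coding_per_sample}"
                for s, c in counts.items() if c > max_coding_per_sample}
    kept = [r for r in records if r.sample_id not in excluded]
    summary = CohortSummary(per_sample_coding=dict(counts), excluded_samples=excluded,
                            n_duplicates_removed=n_dup)
    return kept, summary


def collapse_adjacent(records, distance: int = 1):
    """Collapse same-sample substitutions within ``distance`` bp into MNVs.

    Runs of adjacent substitutions (dinucleotide/complex events from a single
    mutational hit) are merged into one multi-base record, which downstream
    counting treats like an indel-class event rather than independent
    substitutions.
    """
    subs = [r for r in records if r.kind == "substitution"]
    others = [r for r in records if r.kind != "substitution"]
    out = list(others)
    keyed = sorted(subs, key=lambda r: (r.sample_id, r.chromosome, r.position))
    run: list[MutationRecord] = []

    def flush(run):
        if len(run) == 1:
            out.append(run[0])
        elif run:
            ref = "".join(r.ref for r in run)
            alt = "".join(r.alt for r in run)
            out.append(MutationRecord(run[0].sample_id, run[0].chromosome,
                                      run[0].position, ref, alt))

    for r in keyed:
        if run and (r.sample_id, r.chromosome) == (run[-1].sample_id, run[-1].chromosome) \
                and r.position - run[-1].position <= distance:
            run.append(r)
        else:
            flush(run)
            run = [r]
    flush(run)
    return out


@dataclass
class GeneCounts:
    gene_id: str
    n: np.ndarray  # class_count x 4
    n_indel: int = 0
    n_indel_sites: int = 0

    @property
    def n_s(self) -> int:
        return int(self.n[:, 0].sum())

    @property
    def n_m(self) -> int:
        return int(self.n[:, 1].sum())

    @property
    def n_n(self) -> int:
        return int(self.n[:, 2].sum())

    @property
    def n_e(self) -> int:
        return int(self.n[:, 3].sum())

    def marginals(self) -> np.ndarray:
        return self.n.sum(axis=0)


@dataclass
class CountReport:
    n_substitutions_counted: int = 0
    n_indels_counted: int = 0
    n_intergenic: int = 0
    reference_mismatch: list = field(default_factory=list)
    skipped: list = field(default_factory=list)


def count_by_gene(records, genes: list[CodingGene], index: SubstitutionClassIndex,
                  collapse_mnv: bool = True, genome_index: GenomeIndex | None = None):
    """Tally observed mutation counts per gene, class and impact.

    Substitutions are classified by :func:`annotate_substitution`; indels (and
    collapsed MNVs) are assigned by their leftmost base and also tallied as
    unique start sites, the robust recurrence statistic.  Reference-mismatch
    records are excluded and reported.
    """
    if genome_index is None:
        genome_index = GenomeIndex(genes)
    if collapse_mnv:
        records = collapse_adjacent(records, distance=1)
    counts = {g.gene_id: GeneCounts(g.gene_id, np.zeros((index.class_count, 4), dtype=np.int64))
              for g in genes}
    indel_sites: dict[str, set] = defaultdict(set)
    report = CountReport()
    for r in records:
        gene = genome_index.gene_at(r.chromosome, r.position)
        if gene is None and r.kind == "indel":
            # an indel may still touch a gene downstream of its leftmost base
            for off in range(1, len(r.ref)):
                gene = genome_index.gene_at(r.chromosome, r.position + off)
                if gene is not None:
                    break
        if gene is None:
            report.n_intergenic += 1
            continue
        gc = counts[gene.gene_id]
        if r.kind == "substitution":
            try:
                ann = annotate_substitution(gene, r.position, r.ref, r.alt, index)
            except AnnotationError as exc:
                report.reference_mismatch.append((r, str(exc)))
                continue
            gc.n[ann.class_id, IMPACT_INDEX[ann.impact]] += 1
            report.n_substitutions_counted += 1
        else:
            gc.n_indel += 1
            indel_sites[gene.gene_id].add((r.chromosome, r.position))
            report.n_indels_counted += 1
    for gid, sites in indel_sites.items():
        counts[gid].n_indel_sites = len(sites)
    return list(counts.values()), report


def spectrum_96(records, genes: list[CodingGene], genome_index: GenomeIndex | None = None):
    """Pyrimidine-centric 96-channel trinucleotide spectrum of coding substitutions.

    Returns (channel_labels, per_sample DataFrame of counts).
    """
    from .signatures import CHANNELS_96, channel_of
    if genome_index is None:
        genome_index = GenomeIndex(genes)
    per_sample: dict[str, np.ndarray] = defaultdict(lambda: np.zeros(96, dtype=int))
    for r in records:
        if r.kind != "substitution":
            continue
        gene = genome_index.gene_at(r.chromosome, r.position)
        if gene is None:
            continue
        k = gene.cds_index_of(r.position)
        if k is None:
            continue
        from .genome_model import MAX_CONTEXT_WIDTH as MW
        win = gene.context_windows[k]
        up, ref_i, down = int(win[MW - 1]), int(win[MW]), int(win[MW + 1])
        alt = r.alt
        if gene.strand == "-":
            alt = BASES[3 - BASES.index(alt)]
        ch = channel_of(BASES[up], BASES[ref_i], alt, BASES[down])
        per_sample[r.sample_id][ch] += 1
    df = pd.DataFrame(dict(per_sample), index=CHANNELS_96).T
    return CHANNELS_96, df
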