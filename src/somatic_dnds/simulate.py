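"""Neutral and cohort simulators for bias studies and test harnesses.

These generators draw somatic substitutions over the coding sites of a gene
model in proportion to a context-dependent spectrum, with no selection unless
explicitly planted or thinned.  They reproduce the classic failure modes of
dN/dS estimation: simplistic substitution models on context-dependent data,
germline SNP contamination, over-filtering of polymorphic sites, and
heterogeneous cohorts mixing signatures, burdens and selection pressures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog_io import MutationRecord
from .genome_model import (BASES, CodingGene, SubstitutionClassIndex,
                           site_enumeration)


class SimulationError(ValueError):
    pass


@dataclass
class SpectrumProfile:
    """Relative substitution rates per class on the coding strand."""
    name: str
    context_width: int
    rates: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        index = SubstitutionClassIndex(self.context_width)
        if self.rates.shape != (index.class_count,):
            raise SimulationError(
                f"spectrum {self.name!r}: expected {index.class_count} rates")
        if (self.rates < 0).any() or self.rates.sum() == 0:
            raise SimulationError(f"spectrum {self.name!r}: rates must be "
                                  "non-negative and not all zero")

    def to_tsv(self, path) -> None:
        index = SubstitutionClassIndex(self.context_width)
        labels = [index.label(i) for i in range(index.class_count)]
        pd.DataFrame({"class": labels, "rate": self.rates}).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, name=None, context_width=None) -> "SpectrumProfile":
        df = pd.read_csv(path, sep="\t")
        n = len(df)
        width = {12: 0, 192: 1, 3072: 2}.get(n)
        if context_width is not None:
            width = context_width
        if width is None:
            raise SimulationError(f"cannot infer context width from {n} rows")
        index = SubstitutionClassIndex(width)
        rates = np.zeros(index.class_count)
        for cls_label, rate in zip(df.iloc[:, 0], df.iloc[:, 1]):
            rates[_parse_label(str(cls_label), index)] = float(rate)
        return cls(name or "file", width, rates)


def _parse_label(label: str, index: SubstitutionClassIndex) -> int:
    up, rest = label.split("[")
    change, down = rest.split("]")
    ref, alt = change.split(">")
    return index.class_id(up, ref, alt, down)


def _iter_trinucleotide_classes():
    index = SubstitutionClassIndex(1)
    for cid in range(192):
        label = index.label(cid)
        up, ref, alt, down = label[0], label[2], label[4], label[6]
        yield cid, up, ref, alt, down


def _base_rates_ts_tv(ref, alt, transition=3.0, transversion=1.0):
    transitions = {("C", "T"), ("T", "C"), ("A", "G"), ("G", "A")}
    return transition if (ref, alt) in transitions else transversion


def spectrum_preset(name: str, context_width: int = 1) -> SpectrumProfile:
    """Stylized mutational spectra for simulation studies.

    - ``flat``: all classes equal.
    - ``pancancer_like``: transition/transversion bias plus strongly elevated
      C>T at CpG sites (and the complementary G>A with upstream C), with a
      mild transcriptional-strand asymmetry.
    - ``uv_like``: C>T at pyrimidine-preceded cytosines dominates.
    - ``tobacco_like``: elevated G>T (coding strand) / C>A, asymmetric.

    These are design presets, not empirical cohort spectra: they reproduce the
    qualitative context biases the models must withstand.
    """
    if context_width != 1 and name != "flat":
        raise SimulationError("presets other than 'flat' are defined at width 1")
    index = SubstitutionClassIndex(context_width)
    if name == "flat":
        return SpectrumProfile("flat", context_width, np.ones(index.class_count))
    rates = np.zeros(192)
    for cid, up, ref, alt, down in _iter_trinucleotide_classes():
        r = _base_rates_ts_tv(ref, alt)
        if name == "pancancer_like":
            if ref == "C" and alt == "T" and down == "G":
                r *= 20.0
            elif ref == "G" and alt == "A" and up == "C":
                r *= 14.0
        elif name == "uv_like":
            if ref == "C" and alt == "T" and up in "CT":
                r *= 30.0
            elif ref == "G" and alt == "A" and down in "AG":
                r *= 22.0
        elif name == "tobacco_like":
            if ref == "G" and alt == "T":
                r *= 25.0
            elif ref == "C" and alt == "A":
                r *= 12.0
        else:
            raise SimulationError(f"unknown spectrum preset {name!r}")
        rates[cid] = r
    return SpectrumProfile(name, 1, rates)


# --- genome-wide site table -------------------------------------------------


@dataclass
class SiteTable:
    """Flat enumeration of every possible coding/splice substitution."""
    chromosome: np.ndarray
    position: np.ndarray
    ref_genomic: np.ndarray     # base index on the + strand
    alt_genomic: np.ndarray
    class_id: np.ndarray        # coding-strand substitution class
    impact: np.ndarray          # 0 s, 1 m, 2 n, 3 e
    gene_index: np.ndarray
    genes: list = field(default_factory=list)

    def __len__(self):
        return len(self.position)


def build_site_table(genes: list[CodingGene], index: SubstitutionClassIndex) -> SiteTable:
    chroms, pos, ref, alt, cls, imp, gidx = [], [], [], [], [], [], []
    for gi, gene in enumerate(genes):
        s = site_enumeration(gene, index)
        n = len(s["position"])
        r, a = s["ref"], s["alt"]
        if gene.strand == "-":
            r, a = 3 - r, 3 - a
        chroms.append(np.full(n, gi))      # chromosome resolved via gene
        pos.append(s["position"])
        ref.append(r)
        alt.append(a)
        cls.append(s["class_id"])
        imp.append(s["impact"])
        gidx.append(np.full(n, gi))
    return SiteTable(
        chromosome=np.concatenate(chroms), position=np.concatenate(pos),
        ref_genomic=np.concatenate(ref), alt_genomic=np.concatenate(alt),
        class_id=np.concatenate(cls), impact=np.concatenate(imp),
        gene_index=np.concatenate(gidx), genes=list(genes))


def _draw_unique(rng, weights_cum, table: SiteTable, k: int, sample_id: str,
                 max_rounds: int = 200):
    """Draw k distinct-position sites for one sample (duplicates re-drawn)."""
    chosen: dict[tuple, int] = {}
    rounds = 0
    while len(chosen) < k and rounds < max_rounds:
        need = k - len(chosen)
        u = rng.random(need) * weights_cum[-1]
        idx = np.searchsorted(weights_cum, u, side="right")
        for i in idx:
            gene = table.genes[table.gene_index[i]]
            key = (gene.chromosome, int(table.position[i]))
            if key not in chosen:
                chosen[key] = int(i)
        rounds += 1
    records = []
    for (chrom, p), i in chosen.items():
        records.append(MutationRecord(sample_id, chrom, p,
                                      BASES[table.ref_genomic[i]],
                                      BASES[table.alt_genomic[i]]))
    return records, list(chosen.values())


def site_weights(table: SiteTable, spectrum: SpectrumProfile,
                 gene_rate=None, omega_m=None, omega_t=None) -> np.ndarray:
    """Per-site sampling weights: spectrum rate x optional per-gene modifiers.

    ``gene_rate`` is a per-gene multiplier array; ``omega_m``/``omega_t``
    per-gene selection multipliers applied to missense / truncating sites
    (the multiplicative planting of selection used by the cohort fixtures).
    """
    w = spectrum.rates[table.class_id].astype(float)
    if gene_rate is not None:
        w = w * np.asarray(gene_rate, dtype=float)[table.gene_index]
    if omega_m is not None:
        mult = np.asarray(omega_m, dtype=float)[table.gene_index]
        w = np.where(table.impact == 1, w * mult, w)
    if omega_t is not None:
        mult = np.asarray(omega_t, dtype=float)[table.gene_index]
        w = np.where((table.impact == 2) | (table.impact == 3), w * mult, w)
    return w


def simulate_neutral(genes: list[CodingGene], spectrum: SpectrumProfile,
                     n_mutations: int, seed: int, n_samples: int = 1,
                     sample_prefix: str = "S", table: SiteTable | None = None):
    """Draw random coding substitutions with probability proportional to the
    spectrum rate of each site's substitution class; no selection applied.

    Mutations are spread evenly over ``n_samples`` samples; within a sample
    duplicate positions are re-drawn (a somatic catalog is per-sample unique).
    """
    index = SubstitutionClassIndex(spectrum.context_width)
    if table is None:
        table = build_site_table(genes, index)
    w = site_weights(table, spectrum)
    cum = np.cumsum(w)
    if cum[-1] <= 0:
        raise SimulationError("spectrum assigns zero weight to every site")
    rng = np.random.default_rng(seed)
    per = np.full(n_samples, n_mutations // n_samples)
    per[:n_mutations % n_samples] += 1
    records = []
    for s in range(n_samples):
        recs, _ = _draw_unique(rng, cum, table, int(per[s]), f"{sample_prefix}{s:04d}")
        records.extend(recs)
    return records


def draw_class_counts(table: SiteTable, spectrum: SpectrumProfile,
                      n_mutations: int, seed: int) -> np.ndarray:
    """Aggregated neutral counts n[class, impact] from ``n_mutations`` random
    coding substitutions (drawn with replacement across the cohort).

    Fast path for replicate calibration studies that only need the aggregated
    count matrix, not a per-sample catalog.
    """
    index = SubstitutionClassIndex(spectrum.context_width)
    w = site_weights(table, spectrum)
    cum = np.cumsum(w)
    if cum[-1] <= 0:
        raise SimulationError("spectrum assigns zero weight to every site")
    rng = np.random.default_rng(seed)
    u = rng.random(n_mutations) * cum[-1]
    idx = np.searchsorted(cum, u, side="right")
    n = np.zeros((index.class_count, 4), dtype=np.int64)
    np.add.at(n, (table.class_id[idx], table.impact[idx].astype(int)), 1)
    return n


@dataclass
class PatientDesign:
    sample_id: str
    spectrum: SpectrumProfile
    burden: int                  # neutral coding mutations before selection
    omega: float = 1.0           # retention probability of non-synonymous draws

    def __post_init__(self):
        if self.burden < 0:
            raise SimulationError("burden must be >= 0")
        if self.omega > 1:
            raise SimulationError(
                "omega > 1 is not supported by the thinning simulator; plant "
                "positive selection with synthetic_data.generate_cohort instead")
        if self.omega < 0:
            raise SimulationError("omega must be >= 0")


def load_cohort_design(path, spectra: dict | None = None) -> list[PatientDesign]:
    """Read a cohort design from YAML.

    Expected layout: a list of patient entries with keys ``sample_id``,
    ``spectrum`` (a preset name or a key into ``spectra``), ``burden`` and
    optional ``omega``.  Entries may carry a ``replicates`` count to expand
    groups compactly.
    """
    import yaml
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    spectra = spectra or {}
    cache: dict[str, SpectrumProfile] = {}

    def get_spectrum(name: str) -> SpectrumProfile:
        if name in spectra:
            return spectra[name]
        if name not in cache:
            cache[name] = spectrum_preset(name)
        return cache[name]

    design = []
    for entry in payload:
        reps = int(entry.get("replicates", 1))
        for k in range(reps):
            sid = entry["sample_id"] if reps == 1 else f"{entry['sample_id']}{k:03d}"
            design.append(PatientDesign(sid, get_spectrum(str(entry["spectrum"])),
                                        int(entry["burden"]),
                                        float(entry.get("omega", 1.0))))
    return design


def simulate_cohort(design: list[PatientDesign], genes: list[CodingGene],
                    seed: int):
    """Heterogeneous-cohort simulator: per-patient spectra, burdens and selection.

    Each patient receives ``burden`` neutral draws from their spectrum; every
    non-synonymous draw (missense, nonsense, splice) is then retained with
    probability omega.  Returns (records, f_global) where f_global =
    sum_j b_j omega_j / sum_j b_j is the analytic burden-weighted mean of
    selection that a cohort-level dN/dS estimate should recover.
    """
    if not design:
        raise SimulationError("empty cohort design")
    widths = {p.spectrum.context_width for p in design}
    if len(widths) != 1:
        raise SimulationError("all spectra must share a context width")
    index = SubstitutionClassIndex(widths.pop())
    table = build_site_table(genes, index)
    cums = {}
    for p in design:
        if p.spectrum.name not in cums:
            cums[p.spectrum.name] = np.cumsum(site_weights(table, p.spectrum))
    rng = np.random.default_rng(seed)
    records = []
    for p in design:
        recs, idx = _draw_unique(rng, cums[p.spectrum.name], table, p.burden,
                                 p.sample_id)
        nonsyn = table.impact[idx] > 0
        keep = np.ones(len(recs), dtype=bool)
        keep[nonsyn] = rng.random(int(nonsyn.sum())) < p.omega
        records.extend(r for r, k in zip(recs, keep) if k)
    total_b = sum(p.burden for p in design)
    f_global = sum(p.burden * p.omega for p in design) / total_b if total_b else np.nan
    return records, f_global


GERMLINE_PROFILE = {"omega_mis": 0.38, "omega_trunc": 0.08}


def spike_germline(records, genes: list[CodingGene], fraction: float, seed: int,
                   spectrum: SpectrumProfile | None = None,
                   profile: dict = GERMLINE_PROFILE,
                   table: SiteTable | None = None):
    """Contaminate a somatic catalog with germline-SNP-like variants.

    Added variants follow the genome's neutral site expectation reshaped by
    the germline selection profile (missense and truncating sites down-
    weighted by their germline dN/dS), mimicking common SNPs, which are
    heavily enriched in synonymous changes.  ``fraction`` is the fraction of
    the *output* catalog that is germline.
    """
    if not 0 <= fraction < 1:
        raise SimulationError("fraction must be in [0, 1)")
    if fraction == 0:
        return list(records)
    spectrum = spectrum or spectrum_preset("flat")
    index = SubstitutionClassIndex(spectrum.context_width)
    if table is None:
        table = build_site_table(genes, index)
    w = site_weights(table, spectrum)
    mult = np.ones(4)
    mult[1] = profile["omega_mis"]
    mult[2] = mult[3] = profile["omega_trunc"]
    w = w * mult[table.impact]
    cum = np.cumsum(w)
    rng = np.random.default_rng(seed)
    n_add = int(round(len(records) * fraction / (1 - fraction)))
    samples = sorted({r.sample_id for r in records}) or ["S0000"]
    out = list(records)
    u = rng.random(n_add) * cum[-1]
    idx = np.searchsorted(cum, u, side="right")
    for i in idx:
        gene = table.genes[table.gene_index[i]]
        sid = samples[rng.integers(0, len(samples))]
        out.append(MutationRecord(sid, gene.chromosome, int(table.position[i]),
                                  BASES[table.ref_genomic[i]],
                                  BASES[table.alt_genomic[i]]))
    return out


def make_snp_blacklist(genes: list[CodingGene], n_sites: int, seed: int,
                       syn_enrichment: float = 5.0,
                       table: SiteTable | None = None) -> set:
    """Generate a polymorphic-site blacklist enriched for synonymous sites.

    Positions where a synonymous change is possible are over-sampled by
    ``syn_enrichment`` (1.0 gives an impact-balanced control blacklist).
    """
    index = SubstitutionClassIndex(0)
    if table is None:
        table = build_site_table(genes, index)
    df = pd.DataFrame({
        "gene": table.gene_index, "pos": table.position,
        "syn": (table.impact == 0).astype(float)})
    per_pos = df.groupby(["gene", "pos"])["syn"].max().reset_index()
    weights = np.where(per_pos["syn"] > 0, syn_enrichment, 1.0)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    n_sites = min(n_sites, len(per_pos))
    pick = rng.choice(len(per_pos), size=n_sites, replace=False, p=weights)
    out = set()
    for k in pick:
        gene = table.genes[int(per_pos["gene"].iloc[k])]
        out.add((gene.chromosome, int(per_pos["pos"].iloc[k])))
    return out


def overfilter_sites(records, blacklist: set):
    """Remove records at blacklisted (chromosome, position) sites.

    Returns (kept_records, removal_report).  Over-filtering with a
    synonymous-enriched blacklist biases dN/dS upward.
    """
    kept, removed = [], []
    for r in records:
        (removed if (r.chromosome, r.position) in blacklist else kept).append(r)
    return kept, {"n_removed": len(removed), "n_kept": len(kept)}


def randomize_local(records, reference: dict, window_bp: int,
                    context_width: int = 1, seed: int = 0,
                    exclude_positions: set | None = None):
    """Reassign each substitution to a random position with identical sequence
    context within +/- ``window_bp`` of its original position.

    The (2w+1)-mer centred on the mutated base is preserved exactly, so the
    output retains each sample's burden, per-context counts and the regional
    rate variation at the window scale: a neutral dataset.  Mutations with no
    eligible alternative target stay in place and are counted.
    """
    rng = np.random.default_rng(seed)
    w = context_width
    out = []
    n_unmoved = 0
    cache: dict[tuple, np.ndarray] = {}
    for r in records:
        if r.kind != "substitution" or window_bp == 0:
            out.append(r)
            continue
        seq = reference[r.chromosome]
        p0 = r.position - 1
        kmer = seq[p0 - w:p0 + w + 1]
        lo = max(w, p0 - window_bp)
        hi = min(len(seq) - w - 1, p0 + window_bp)
        key = (r.chromosome, lo, hi, kmer)
        if key in cache:
            candidates = cache[key]
        else:
            sub = seq[lo - w:hi + w + 1]
            candidates = np.array(
                [lo + i for i in range(hi - lo + 1)
                 if sub[i:i + 2 * w + 1] == kmer], dtype=int)
            cache[key] = candidates
        pool = candidates
        if exclude_positions:
            pool = np.array([c for c in candidates
                             if (r.chromosome, c + 1) not in exclude_positions
                             or c == p0], dtype=int)
        if len(pool) <= 1:
            n_unmoved += 1
            out.append(r)
            continue
        new_p0 = int(pool[rng.integers(0, len(pool))])
        out.append(MutationRecord(r.sample_id, r.chromosome, new_p0 + 1, r.ref, r.alt))
    return out, {"n_unmoved": n_unmoved}
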