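"""Synthetic paired immunized/control VNAR repertoires with ground truth.

The generator emulates the statistical structure of an immunized
phage-display library sequenced on a paired-end short-read instrument:

* a highly skewed clone-abundance distribution — variant read counts
  follow a truncated Zipf law whose exponent is solved so that a
  configurable fraction (default 90%) of unique sequences are singletons;
* clonally expanded lineages of point-mutation variants around a seed
  clone, the seed being the most abundant variant;
* cysteine-architecture subtypes in configurable proportions, Type II
  dominant by default;
* CDR3 lengths uniform on 5-25 residues with a rare ultralong tail
  (>80 aa), so the Tukey whiskers of the length distribution sit at 5
  and 25;
* target-specific expanded lineages present only in the target library,
  and a small set of shared lineages giving <0.2% sequence sharing.

Every generated molecule is recorded in a :class:`SyntheticTruth`
manifest, which recovery tests compare against pipeline output.

Randomized scaffold positions avoid C, W and Y: cysteines and the CDR1
tryptophan are the subtype-defining residues, and a chance Tyr-Tyr next
to a cysteine could mimic the canonical-Cys2 context motif. Every
emitted variant is additionally re-annotated and resampled on the rare
mismatch, so manifests are always consistent with their sequences.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from . import annotation as ann
from .annotation import RegionAnnotation, Unannotatable, annotate_regions
from .config import DEFAULT_FLANK3, DEFAULT_FLANK5
from .repertoire import RepertoireTable, table_from_counts
from .stats import AffinityRecord

# ---------------------------------------------------------------------------
# scaffold templates
# ---------------------------------------------------------------------------

#: Fixed nurse-shark-like framework blocks (synthetic germline).
FR1_TEMPLATE = "ARVDQTPRTATKETGESLTINC"   # canonical Cys1 at index 21
FR2_TEMPLATE = "TYWYRKNP"
HV2_TEMPLATE = "SGSKEE"
FR3A_TEMPLATE = "FSLRIKDLTV"
HV4_TEMPLATE = "SGNKE"
FR3B_TEMPLATE = "RDSGTYYC"                # canonical Cys2 is the final C
FR4_TEMPLATE = "DGAGTVLTVN"               # starts with the FR4 motif

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Randomized CDR1 positions: no C (subtype-defining) and no W (Type III motif).
CDR1_ALPHABET = "".join(a for a in _AA20 if a not in "CW")
#: Randomized CDR3 positions: no C and no Y (Cys2 context mimicry).
CDR3_ALPHABET = "".join(a for a in _AA20 if a not in "CY")
#: Substitution alphabet for point mutations.
SUB_ALPHABET = "".join(a for a in _AA20 if a not in "CWY")

SUBTYPES = ("I", "II", "III", "IV")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic library pair."""

    n_background_lineages: int = 2000
    n_target_specific_lineages: int = 4
    n_shared_lineages: int = 4
    target_lineage_n_variants: int = 40
    target_lineage_cdr3_len: int = 14
    target_lineage_seed_count: int = 4000
    target_lineage_count_decay: float = 1.1
    shared_lineage_count: int = 50
    background_expansion_prob: float = 0.15
    background_max_variants: int = 8
    mutation_rate: float = 0.02          # per residue per variant
    clonotype_identity_threshold: float = 85.0
    zipf_exponent: Optional[float] = None  # None: solve from singleton_fraction
    zipf_max: int = 10000
    singleton_fraction: float = 0.90
    subtype_mix: Dict[str, float] = field(
        default_factory=lambda: {"I": 0.15, "II": 0.55, "III": 0.15, "IV": 0.15})
    cdr3_len_min: int = 5
    cdr3_len_max: int = 25
    ultralong_prob: float = 0.003
    ultralong_min: int = 81
    ultralong_max: int = 90
    read_length: int = 300
    sequencing_error_rate: float = 0.001
    coverage: int = 1                    # read pairs per counted molecule
    quality_phred: int = 30
    quality_mode: str = "constant"       # constant | degrading
    min_overlap_nt: int = 15
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    rng_seed: int = 2025

    def __post_init__(self) -> None:
        if abs(sum(self.subtype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("subtype_mix must sum to 1")
        for rate in (self.mutation_rate, self.sequencing_error_rate,
                     self.ultralong_prob, self.background_expansion_prob):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not 0.0 < self.singleton_fraction < 1.0:
            raise ValueError("singleton_fraction must be in (0, 1)")

    @classmethod
    def calibration(cls, n_unique: int = 10000, rng_seed: int = 2025,
                    **overrides) -> "GeneratorConfig":
        """Unexpanded single-library conditions for statistical calibration."""
        return cls(
            n_background_lineages=n_unique,
            n_target_specific_lineages=0,
            n_shared_lineages=0,
            background_expansion_prob=0.0,
            rng_seed=rng_seed,
            **overrides,
        )


@dataclass
class Lineage:
    lineage_id: str
    seed_protein: str
    variants: List[Tuple[str, int]]       # (protein, read count), seed first
    library: str                          # target | control | both
    subtype: str
    cdr3: str
    regions: RegionAnnotation


@dataclass
class SyntheticTruth:
    library_id: str
    lineages: List[Lineage] = field(default_factory=list)

    def unique_counts(self) -> Counter:
        tally: Counter = Counter()
        for lineage in self.lineages:
            for protein, count in lineage.variants:
                tally[protein] += count
        return tally


@dataclass
class LibraryPair:
    target_truth: SyntheticTruth
    target_table: RepertoireTable
    control_truth: SyntheticTruth
    control_table: RepertoireTable


# ---------------------------------------------------------------------------
# abundance model
# ---------------------------------------------------------------------------

def solve_zipf_exponent(singleton_fraction: float, zipf_max: int) -> float:
    """Exponent a with P(count=1) = 1/sum_{k<=max} k^-a = singleton_fraction."""
    ks = np.arange(1, zipf_max + 1, dtype=float)

    def f(a: float) -> float:
        return 1.0 / np.sum(ks ** -a) - singleton_fraction

    return float(brentq(f, 1.5, 12.0, xtol=1e-10))


class _ZipfSampler:
    def __init__(self, config: GeneratorConfig):
        a = (config.zipf_exponent if config.zipf_exponent is not None
             else solve_zipf_exponent(config.singleton_fraction, config.zipf_max))
        self.exponent = a
        ks = np.arange(1, config.zipf_max + 1, dtype=float)
        weights = ks ** -a
        self.probs = weights / weights.sum()
        self.support = np.arange(1, config.zipf_max + 1)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(self.support, size=size, p=self.probs)


# ---------------------------------------------------------------------------
# scaffolds and lineages
# ---------------------------------------------------------------------------

def _random_string(rng: np.random.Generator, alphabet: str, length: int) -> str:
    idx = rng.integers(0, len(alphabet), size=length)
    return "".join(alphabet[i] for i in idx)


def _place_subtype_cysteines(subtype: str, cdr1: str, cdr3: str) -> Tuple[str, str, str, str]:
    """Return (cdr1, fr2, cdr3, fr4) with subtype-defining residues placed."""
    fr2, fr4 = FR2_TEMPLATE, FR4_TEMPLATE
    if subtype == "I":
        fr2 = fr2[:5] + "C" + fr2[6:]
        fr4 = fr4[:7] + "C" + fr4[8:]
        if len(cdr3) >= 4:
            pos = (1, len(cdr3) - 2)
        else:
            pos = (0, len(cdr3) - 1)
        for p in pos:
            cdr3 = cdr3[:p] + "C" + cdr3[p + 1:]
    elif subtype in ("II", "III"):
        cdr1 = cdr1[:2] + "C" + cdr1[3:]
        mid = len(cdr3) // 2
        cdr3 = cdr3[:mid] + "C" + cdr3[mid + 1:]
        if subtype == "III":
            cdr1 = cdr1[:4] + "W" + cdr1[5:]
    elif subtype != "IV":
        raise ValueError(f"unknown subtype {subtype!r}")
    return cdr1, fr2, cdr3, fr4


def build_scaffold(subtype: str, cdr3_len: int,
                   rng: np.random.Generator) -> Tuple[str, RegionAnnotation]:
    """A clean VNAR protein of the given subtype with known region truth."""
    if cdr3_len < 2:
        raise ValueError("cdr3_len must be >= 2")
    for _ in range(100):
        cdr1 = _random_string(rng, CDR1_ALPHABET, ann.CDR1_LEN)
        cdr3 = _random_string(rng, CDR3_ALPHABET, cdr3_len)
        cdr1, fr2, cdr3, fr4 = _place_subtype_cysteines(subtype, cdr1, cdr3)
        protein = (FR1_TEMPLATE + cdr1 + fr2 + HV2_TEMPLATE + FR3A_TEMPLATE
                   + HV4_TEMPLATE + FR3B_TEMPLATE + cdr3 + fr4)
        regions = annotate_regions(protein)
        if isinstance(regions, Unannotatable):
            continue
        start, end = regions.cdr3
        if protein[start:end] != cdr3:
            continue
        profile = ann.cysteine_profile(protein, regions)
        if ann.classify_subtype(profile).subtype == subtype:
            return protein, regions
    raise RuntimeError(f"could not build an unambiguous subtype {subtype} scaffold")


def _max_cdr3_mutations(cdr3_len: int, threshold: float) -> int:
    """Largest mutation count keeping Hamming identity strictly > threshold."""
    cap = int(math.floor(cdr3_len * (1.0 - threshold / 100.0)))
    while cap > 0 and 100.0 * (cdr3_len - cap) <= threshold * cdr3_len:
        cap -= 1
    return max(cap, 0)


def _mutable_positions(protein: str, regions: RegionAnnotation) -> List[int]:
    protected = {regions.canonical_cys1, regions.canonical_cys2,
                 regions.canonical_cys2 - 1, regions.canonical_cys2 - 2}
    fr4_start = regions.intervals["FR4"][0]
    protected.update(range(fr4_start, fr4_start + len(ann.FR4_MOTIF)))
    c1s, c1e = regions.cdr1
    out = []
    for i, aa in enumerate(protein):
        if i in protected or aa == "C":
            continue
        if aa == "W" and c1s <= i < c1e:
            continue  # the Type III CDR1 motif residue
        out.append(i)
    return out


def expand_lineage(seed_protein: str, n_variants: int, mutation_rate: float,
                   rng: np.random.Generator,
                   max_cdr3_mutations: Optional[int] = None) -> List[str]:
    """Point-mutation variants of a seed clone; the seed comes first.

    Mutations avoid the anchor cysteines, the Cys2 context, the FR4 motif
    and subtype-defining residues; each variant is unique, re-annotates to
    the seed's CDR3 interval and subtype, and (when capped) keeps its CDR3
    within the configured identity of the seed.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    regions = annotate_regions(seed_protein)
    if isinstance(regions, Unannotatable):
        raise ValueError(f"seed not annotatable: {regions.reason}")
    c3s, c3e = regions.cdr3
    seed_subtype = ann.classify_subtype(
        ann.cysteine_profile(seed_protein, regions)).subtype
    mutable = _mutable_positions(seed_protein, regions)
    variants = [seed_protein]
    seen = {seed_protein}
    while len(variants) < n_variants:
        for _ in range(500):
            n_mut = max(1, int(rng.binomial(len(seed_protein), mutation_rate)))
            n_mut = min(n_mut, len(mutable))
            pos = rng.choice(len(mutable), size=n_mut, replace=False)
            positions = [mutable[p] for p in pos]
            if max_cdr3_mutations is not None:
                if sum(1 for p in positions if c3s <= p < c3e) > max_cdr3_mutations:
                    continue
            chars = list(seed_protein)
            for p in positions:
                choices = [a for a in SUB_ALPHABET if a != chars[p]]
                chars[p] = choices[int(rng.integers(0, len(choices)))]
            candidate = "".join(chars)
            if candidate in seen:
                continue
            cand_regions = annotate_regions(candidate)
            if isinstance(cand_regions, Unannotatable):
                continue
            if cand_regions.cdr3 != (c3s, c3e):
                continue
            if ann.classify_subtype(
                    ann.cysteine_profile(candidate, cand_regions)).subtype != seed_subtype:
                continue
            seen.add(candidate)
            variants.append(candidate)
            break
        else:
            raise RuntimeError("could not generate a consistent lineage variant")
    return variants


# ---------------------------------------------------------------------------
# library pair generation
# ---------------------------------------------------------------------------

def _sample_cdr3_len(config: GeneratorConfig, rng: np.random.Generator) -> int:
    if rng.random() < config.ultralong_prob:
        return int(rng.integers(config.ultralong_min, config.ultralong_max + 1))
    return int(rng.integers(config.cdr3_len_min, config.cdr3_len_max + 1))


def _sample_subtype(config: GeneratorConfig, rng: np.random.Generator) -> str:
    probs = [config.subtype_mix.get(s, 0.0) for s in SUBTYPES]
    return SUBTYPES[int(rng.choice(len(SUBTYPES), p=probs))]


def _planted_counts(config: GeneratorConfig, n: int) -> List[int]:
    return [max(1, round(config.target_lineage_seed_count
                         * (i + 1) ** -config.target_lineage_count_decay))
            for i in range(n)]


def _background_lineage(prefix: str, index: int, config: GeneratorConfig,
                        rng: np.random.Generator, zipf: _ZipfSampler,
                        library: str) -> Lineage:
    subtype = _sample_subtype(config, rng)
    cdr3_len = _sample_cdr3_len(config, rng)
    seed, regions = build_scaffold(subtype, cdr3_len, rng)
    n_variants = 1
    if config.background_expansion_prob > 0 and rng.random() < config.background_expansion_prob:
        n_variants = 2 + int(rng.geometric(0.5))
        n_variants = min(n_variants, config.background_max_variants)
    proteins = (expand_lineage(seed, n_variants, config.mutation_rate, rng)
                if n_variants > 1 else [seed])
    counts = zipf.sample(rng, len(proteins))
    # the seed is the lineage's most abundant variant
    counts = sorted((int(c) for c in counts), reverse=True)
    s, e = regions.cdr3
    return Lineage(
        lineage_id=f"{prefix}{index}",
        seed_protein=seed,
        variants=list(zip(proteins, counts)),
        library=library,
        subtype=subtype,
        cdr3=seed[s:e],
        regions=regions,
    )


def generate_library_pair(config: GeneratorConfig) -> LibraryPair:
    """Generate the target/control truth manifests and repertoire tables."""
    rng = np.random.default_rng(config.rng_seed)
    zipf = _ZipfSampler(config)
    cap = _max_cdr3_mutations(config.target_lineage_cdr3_len,
                              config.clonotype_identity_threshold)

    target = SyntheticTruth(library_id="target")
    control = SyntheticTruth(library_id="control")

    # expanded target-specific lineages (the planted discovery signal)
    for i in range(config.n_target_specific_lineages):
        seed, regions = build_scaffold("II", config.target_lineage_cdr3_len, rng)
        proteins = expand_lineage(seed, config.target_lineage_n_variants,
                                  config.mutation_rate, rng, max_cdr3_mutations=cap)
        counts = _planted_counts(config, len(proteins))
        s, e = regions.cdr3
        target.lineages.append(Lineage(
            lineage_id=f"T{i + 1}", seed_protein=seed,
            variants=list(zip(proteins, counts)), library="target",
            subtype="II", cdr3=seed[s:e], regions=regions))

    # shared lineages, present in both libraries
    for i in range(config.n_shared_lineages):
        seed, regions = build_scaffold(
            _sample_subtype(config, rng), config.target_lineage_cdr3_len, rng)
        s, e = regions.cdr3
        profile = ann.cysteine_profile(seed, regions)
        subtype = ann.classify_subtype(profile).subtype
        for truth in (target, control):
            truth.lineages.append(Lineage(
                lineage_id=f"S{i + 1}", seed_protein=seed,
                variants=[(seed, config.shared_lineage_count)], library="both",
                subtype=subtype, cdr3=seed[s:e], regions=regions))

    # independent backgrounds
    for i in range(config.n_background_lineages):
        target.lineages.append(
            _background_lineage("B", i + 1, config, rng, zipf, "target"))
    for i in range(config.n_background_lineages):
        control.lineages.append(
            _background_lineage("K", i + 1, config, rng, zipf, "control"))

    target_table = table_from_counts(target.unique_counts(), "target")
    control_table = table_from_counts(control.unique_counts(), "control")
    return LibraryPair(target, target_table, control, control_table)


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

_CODONS: Dict[str, List[str]] = {}


def _codon_table() -> Dict[str, List[str]]:
    if not _CODONS:
        from Bio.Data.CodonTable import standard_dna_table

        for codon, aa in sorted(standard_dna_table.forward_table.items()):
            _CODONS.setdefault(aa, []).append(codon)
    return _CODONS


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform random synonymous codon choice, seeded for determinism."""
    table = _codon_table()
    parts = []
    for aa in protein:
        codons = table[aa]
        parts.append(codons[int(rng.integers(0, len(codons)))])
    return "".join(parts)


_DNA = "ACGT"


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in positions:
        alternatives = [b for b in _DNA if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def _qual_string(length: int, config: GeneratorConfig) -> str:
    base = chr(config.quality_phred + 33)
    if config.quality_mode == "constant":
        return base * length
    # degrading tail: last 30 bases drop to Q2 (for trim tests)
    tail = min(30, length)
    return base * (length - tail) + chr(2 + 33) * tail


def emit_reads(truth: SyntheticTruth, config: GeneratorConfig,
               path_fwd, path_rev,
               rng: Optional[np.random.Generator] = None) -> List[Tuple[str, str, int]]:
    """Write a paired FASTQ file couple for one library.

    Each counted molecule yields ``coverage`` read pairs: the variant is
    reverse-translated once, flanked by the conserved anchors, and split
    into a forward read and a reverse-complemented reverse read with
    substitution errors at the configured rate. Returns the manifest of
    (read id, lineage id, variant index).
    """
    from .io import write_fastq
    from .reads import revcomp

    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    max_amplicon = 2 * config.read_length - config.min_overlap_nt
    fwd_records: List[Tuple[str, str, str]] = []
    rev_records: List[Tuple[str, str, str]] = []
    manifest: List[Tuple[str, str, int]] = []
    for lineage in truth.lineages:
        for vi, (protein, count) in enumerate(lineage.variants):
            nt = reverse_translate(protein, rng)
            amplicon = config.flank5 + nt + config.flank3
            if len(amplicon) > max_amplicon:
                raise ValueError(
                    f"lineage {lineage.lineage_id}: amplicon length "
                    f"{len(amplicon)} exceeds {max_amplicon} for an overlapping pair")
            span = min(config.read_length, len(amplicon))
            fwd_t = amplicon[:span]
            rev_t = revcomp(amplicon)[:span]
            for k in range(count * config.coverage):
                rid = f"{truth.library_id}:{lineage.lineage_id}:{vi}:{k}"
                fwd = _add_errors(fwd_t, config.sequencing_error_rate, rng)
                rev = _add_errors(rev_t, config.sequencing_error_rate, rng)
                fwd_records.append((rid + "/1", fwd, _qual_string(len(fwd), config)))
                rev_records.append((rid + "/2", rev, _qual_string(len(rev), config)))
                manifest.append((rid, lineage.lineage_id, vi))
    write_fastq(path_fwd, fwd_records)
    write_fastq(path_rev, rev_records)
    return manifest


def write_truth_manifest(truth: SyntheticTruth, path) -> None:
    """Ground-truth lineage/variant table as TSV."""
    import pandas as pd

    rows = []
    for lineage in truth.lineages:
        for vi, (protein, count) in enumerate(lineage.variants):
            rows.append({
                "library": truth.library_id,
                "lineage_id": lineage.lineage_id,
                "variant_index": vi,
                "count": count,
                "subtype": lineage.subtype,
                "cdr3": lineage.cdr3,
                "sequence": protein,
            })
    pd.DataFrame(rows, columns=["library", "lineage_id", "variant_index",
                                "count", "subtype", "cdr3", "sequence"]
                 ).to_csv(path, sep="\t", index=False)


def synthetic_affinity_records(truth: SyntheticTruth,
                               rng: np.random.Generator,
                               n: int = 10) -> List[AffinityRecord]:
    """Synthetic prevalence/affinity panel over the expanded lineage seeds.

    Affinity is modelled as KD inversely proportional to NGS prevalence
    with lognormal scatter, and Sanger hit repeats as a noisy downsampling
    of prevalence — the qualitative relationships the correlation analyses
    probe. Entirely synthetic; no measured affinities stand behind it.
    """
    planted = [lin for lin in truth.lineages if lin.lineage_id.startswith(("T", "S"))]
    pool = []
    for lin in planted:
        for vi, (protein, count) in enumerate(lin.variants[:3]):
            pool.append((count, f"{lin.lineage_id}.{vi}"))
    pool.sort(key=lambda t: (-t[0], t[1]))
    records = []
    for count, clone_id in pool[:n]:
        kd = 1e-6 / count * float(rng.lognormal(0.0, 0.4))
        sanger = max(1, int(rng.poisson(count / 500.0)))
        records.append(AffinityRecord(clone_id=clone_id, kd=kd,
                                      ngs_repeats=count, sanger_repeats=sanger))
    return records
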