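"""Sample-to-individual pipeline for non-invasive fecal DNA genotypes.

Fecal DNA is degraded, so the lab workflow screens samples by qPCR
quality (both extractions must amplify at C_t <= 36), genotypes each
passing sample in replicate PCRs (multi-tube approach), calls a
consensus multilocus genotype, and assigns samples to individuals.
Samples whose genotypes differ at a single allele are merged only when
the mismatching locus was heterozygous in at least one replicate of
either sample — the signature of allelic dropout; two or more allele
differences always separate individuals.  The sibling identity
probability P_IDsib measures whether the marker panel can distinguish
full siblings, which matters because pigs travel in family groups
(sounders).
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from wildens.closed_cr import CaptureHistory

log = logging.getLogger(__name__)

CT_MAX_DEFAULT = 36.0
MIN_LOCI_DEFAULT = 8  # operationalizes "typed at more than 7 loci"

AllelePair = tuple[int, int]


def _norm_pair(pair) -> AllelePair | None:
    if pair is None:
        return None
    a, b = pair
    if a is None or b is None:
        return None
    return (min(a, b), max(a, b))


@dataclass
class GenotypeSample:
    """One fecal sample: qPCR quality plus replicate multilocus genotypes.

    ``replicates`` maps each replicate PCR to {locus: (allele, allele) or
    None}; allele pairs are unordered, ``None`` marks a failed locus.
    """

    sample_id: str
    transect: int
    occasion: int
    habitat: str
    ct_values: tuple[float, float]
    replicates: list[dict]

    def __post_init__(self) -> None:
        if len(self.ct_values) != 2:
            raise ValueError("exactly two extractions (two C_t values) per sample")
        if not self.replicates:
            raise ValueError("at least one replicate genotype required")
        panel = set(self.replicates[0])
        for rep in self.replicates[1:]:
            if set(rep) != panel:
                raise ValueError("all replicates must share the locus panel")
        self.replicates = [
            {locus: _norm_pair(pair) for locus, pair in rep.items()} for rep in self.replicates
        ]

    @property
    def loci(self) -> list[str]:
        return sorted(self.replicates[0])


@dataclass
class ConsensusGenotype:
    """Consensus multilocus genotype with replicate provenance.

    ``het_in_replicates`` lists loci where any replicate showed a
    heterozygote; the 1-mismatch merge rule consults it.
    """

    sample_id: str
    consensus: dict
    transect: int | None = None
    occasion: int | None = None
    habitat: str | None = None
    het_in_replicates: frozenset = field(default_factory=frozenset)

    @property
    def n_typed_loci(self) -> int:
        return sum(1 for v in self.consensus.values() if v is not None)

    def typed_loci(self) -> set:
        return {k for k, v in self.consensus.items() if v is not None}


def screen_qpcr(
    samples: list[GenotypeSample], ct_max: float = CT_MAX_DEFAULT
) -> list[GenotypeSample]:
    """Keep samples whose both C_t values are <= ct_max (inclusive)."""
    passing = []
    for s in samples:
        cts = s.ct_values
        if any(c is None or not np.isfinite(c) for c in cts):
            log.warning("sample %s rejected: missing C_t value", s.sample_id)
            continue
        if all(c <= ct_max for c in cts):
            passing.append(s)
    return passing


def consensus_genotype(
    sample: GenotypeSample, min_replicates_per_allele: int = 2
) -> ConsensusGenotype:
    """Call a consensus genotype from replicate PCRs.

    An allele is supported by a replicate when it appears in that
    replicate's pair.  A heterozygote call requires each of the two
    alleles supported by >= ``min_replicates_per_allele`` replicates;
    a homozygote the same for its single allele.  Loci with no
    sufficiently supported allele are left missing.
    """
    consensus: dict = {}
    het_loci = set()
    for locus in sample.loci:
        support: Counter = Counter()
        for rep in sample.replicates:
            pair = rep.get(locus)
            if pair is None:
                continue
            if pair[0] != pair[1]:
                het_loci.add(locus)
            for allele in set(pair):
                support[allele] += 1
        confirmed = sorted(
            (a for a, k in support.items() if k >= min_replicates_per_allele),
            key=lambda a: (-support[a], a),
        )
        if len(confirmed) >= 2:
            a, b = confirmed[0], confirmed[1]
            consensus[locus] = (min(a, b), max(a, b))
        elif len(confirmed) == 1:
            consensus[locus] = (confirmed[0], confirmed[0])
        else:
            consensus[locus] = None
    return ConsensusGenotype(
        sample_id=sample.sample_id,
        consensus=consensus,
        transect=sample.transect,
        occasion=sample.occasion,
        habitat=sample.habitat,
        het_in_replicates=frozenset(het_loci),
    )


def allele_mismatch(g1: ConsensusGenotype, g2: ConsensusGenotype):
    """Count mismatched alleles over loci typed in both genotypes.

    Per locus the mismatch is the minimum number of allele substitutions
    turning one unordered pair into the other (0, 1 or 2).
    """
    shared = g1.typed_loci() & g2.typed_loci()
    if not shared:
        raise ValueError(
            f"no shared typed loci between {g1.sample_id} and {g2.sample_id}"
        )
    total = 0
    mismatch_loci = []
    for locus in sorted(shared):
        a = Counter(g1.consensus[locus])
        b = Counter(g2.consensus[locus])
        overlap = sum((a & b).values())
        d = 2 - overlap
        if d:
            total += d
            mismatch_loci.append(locus)
    return total, mismatch_loci


@dataclass
class MatchReport:
    """Partition of samples into individuals plus dropout-flagged pairs."""

    individuals: list[list[str]]
    putative_matches: list[tuple[str, str, list]]
    excluded: list[str]

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)


def match_individuals(
    genotypes: list[ConsensusGenotype],
    min_loci: int = MIN_LOCI_DEFAULT,
    merge_putative: bool = True,
) -> MatchReport:
    """Partition consensus genotypes into individuals.

    Exact multilocus matches merge.  Pairs differing at exactly one
    allele merge only when the mismatching locus was heterozygous in a
    replicate of either sample (putative allelic dropout); those pairs
    are additionally reported for verification re-runs.  Pairs differing
    at >= 2 alleles never merge.  Merging is closed transitively.
    Samples typed at fewer than ``min_loci`` loci are excluded.
    """
    kept = sorted(
        (g for g in genotypes if g.n_typed_loci >= min_loci), key=lambda g: g.sample_id
    )
    excluded = sorted(
        g.sample_id for g in genotypes if g.n_typed_loci < min_loci
    )
    parent = {g.sample_id: g.sample_id for g in kept}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            # deterministic root: lexicographically smaller id wins
            lo, hi = sorted((ra, rb))
            parent[hi] = lo

    putative = []
    for g1, g2 in itertools.combinations(kept, 2):
        try:
            d, loci = allele_mismatch(g1, g2)
        except ValueError:
            continue
        if d == 0:
            union(g1.sample_id, g2.sample_id)
        elif d == 1:
            locus = loci[0]
            if locus in g1.het_in_replicates or locus in g2.het_in_replicates:
                putative.append((g1.sample_id, g2.sample_id, loci))
                if merge_putative:
                    union(g1.sample_id, g2.sample_id)

    groups = defaultdict(list)
    for g in kept:
        groups[find(g.sample_id)].append(g.sample_id)
    individuals = sorted(sorted(v) for v in groups.values())
    return MatchReport(individuals=individuals, putative_matches=putative, excluded=excluded)


def p_sib(freqs: dict) -> tuple[dict, float]:
    """Sibling identity probability per locus and the multilocus product.

    Per locus with allele frequencies p_i:
        P = 0.25 + 0.5*S2 + 0.5*S2^2 - 0.25*S4,  S2 = sum p_i^2, S4 = sum p_i^4.
    The product over loci is the probability two full siblings share the
    complete multilocus genotype by descent and chance.
    """
    per_locus = {}
    overall = 1.0
    for locus, p in freqs.items():
        p = np.asarray(p, dtype=float)
        if (p < 0).any() or (p > 1).any():
            raise ValueError(f"frequencies at {locus} outside [0,1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies at {locus} sum to {p.sum():.12f}, not 1")
        s2 = float((p**2).sum())
        s4 = float((p**4).sum())
        val = 0.25 + 0.5 * s2 + 0.5 * s2**2 - 0.25 * s4
        per_locus[locus] = val
        overall *= val
    return per_locus, overall


def build_capture_history(
    report: MatchReport,
    samples: list[GenotypeSample] | list[ConsensusGenotype],
    n_occasions: int,
) -> dict[str, CaptureHistory]:
    """Collapse the sample partition into per-habitat detection matrices.

    Multiple samples of one individual on one occasion count once
    (same-day duplicates are not redetections).  An individual is
    assigned to the habitat where it was sampled; habitats are assumed
    spatially independent, matching the field design.
    """
    meta = {s.sample_id: s for s in samples}
    by_habitat: dict[str, dict[str, set[int]]] = defaultdict(dict)
    for members in report.individuals:
        ind_id = members[0]
        habitats = defaultdict(set)
        for sid in members:
            s = meta[sid]
            habitats[s.habitat].add(s.occasion)
        for hab, occs in habitats.items():
            by_habitat[hab][ind_id] = occs

    out = {}
    for hab, individuals in sorted(by_habitat.items()):
        ids = sorted(individuals)
        mat = np.zeros((len(ids), n_occasions), dtype=int)
        for i, ind in enumerate(ids):
            for occ in individuals[ind]:
                if not 1 <= occ <= n_occasions:
                    raise ValueError(f"occasion {occ} outside 1..{n_occasions}")
                mat[i, occ - 1] = 1
        out[hab] = CaptureHistory(hab, mat, n_occasions, individual_ids=ids)
    return out


def read_genotype_csv(path: str) -> list[GenotypeSample]:
    """Read the long-format genotype CSV.

    Columns: sample_id, transect, occasion, habitat, ct1, ct2,
    replicate, locus, allele1, allele2 (blank allele = missing locus).
    """
    df = pd.read_csv(path)
    samples = []
    for sid, g in df.groupby("sample_id", sort=True):
        first = g.iloc[0]
        reps = []
        for _, rep_g in g.groupby("replicate", sort=True):
            geno = {}
            for _, row in rep_g.iterrows():
                if pd.isna(row["allele1"]) or pd.isna(row["allele2"]):
                    geno[row["locus"]] = None
                else:
                    geno[row["locus"]] = (int(row["allele1"]), int(row["allele2"]))
            reps.append(geno)
        samples.append(
            GenotypeSample(
                sample_id=str(sid),
                transect=int(first["transect"]),
                occasion=int(first["occasion"]),
                habitat=str(first["habitat"]),
                ct_values=(float(first["ct1"]), float(first["ct2"])),
                replicates=reps,
            )
        )
    return samples


def write_genotype_csv(samples: list[GenotypeSample], path: str) -> None:
    rows = []
    for s in samples:
        for r_i, rep in enumerate(s.replicates, start=1):
            for locus in s.loci:
                pair = rep[locus]
                rows.append(
                    {
                        "sample_id": s.sample_id,
                        "transect": s.transect,
                        "occasion": s.occasion,
                        "habitat": s.habitat,
                        "ct1": s.ct_values[0],
                        "ct2": s.ct_values[1],
                        "replicate": r_i,
                        "locus": locus,
                        "allele1": None if pair is None else pair[0],
                        "allele2": None if pair is None else pair[1],
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


__all__ = [
    "CT_MAX_DEFAULT",
    "MIN_LOCI_DEFAULT",
    "GenotypeSample",
    "ConsensusGenotype",
    "MatchReport",
    "screen_qpcr",
    "consensus_genotype",
    "allele_mismatch",
    "match_individuals",
    "p_sib",
    "build_capture_history",
    "read_genotype_csv",
    "write_genotype_csv",
]
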