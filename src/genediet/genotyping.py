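"""PCR-RFLP genotype calling for the FADS2 rs174583 C/T variant and
cohort-level allele statistics.

TauI digestion of the 572-bp amplicon cuts the C allele into 192- and
380-bp fragments and leaves the T allele uncut, so on a gel:

* CC -> {192, 380}
* TT -> {572}
* CT -> {192, 380, 572}

Observed band sizes are matched to these expected lengths within a
configurable tolerance (default +-10 bp) emulating gel resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log

import numpy as np
import pandas as pd

#: fragment lengths in bp; the two cut fragments sum to the amplicon
AMPLICON_BP = 572
CUT_FRAGMENTS_BP = (192, 380)

EXPECTED_PATTERNS = {
    "CC": frozenset(CUT_FRAGMENTS_BP),
    "TT": frozenset({AMPLICON_BP}),
    "CT": frozenset(CUT_FRAGMENTS_BP) | {AMPLICON_BP},
}

GENOTYPES = ("CC", "CT", "TT")

ALLELE_PAIRS = {"CC": ("C", "C"), "CT": ("C", "T"), "TT": ("T", "T")}


class NoEvidenceError(ValueError):
    """Empty fragment set: nothing to call."""


class UncallableError(ValueError):
    """Observed fragment pattern matches none of the canonical patterns."""


@dataclass(frozen=True)
class GenotypeCall:
    genotype: str  # CC / CT / TT
    evidence: frozenset  # observed fragment lengths, bp
    alleles: tuple[str, str]


def call_genotype(fragments, tolerance: float = 10.0) -> GenotypeCall:
    """Call CC/CT/TT from a set of observed RFLP band sizes (bp).

    Each observed length is matched to the nearest expected length
    (192, 380 or 572 bp) within ``tolerance``; the matched set must
    equal one of the three canonical patterns exactly, otherwise the
    pattern is contradictory and rejected.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    obs = frozenset(float(f) for f in fragments)
    if not obs:
        raise NoEvidenceError("no fragments observed")
    expected = (CUT_FRAGMENTS_BP[0], CUT_FRAGMENTS_BP[1], AMPLICON_BP)
    matched = set()
    for f in obs:
        dists = [abs(f - e) for e in expected]
        best = int(np.argmin(dists))
        if dists[best] > tolerance:
            raise UncallableError(f"fragment {f:g} bp matches no expected length within +-{tolerance:g} bp")
        matched.add(expected[best])
    for geno, pattern in EXPECTED_PATTERNS.items():
        if matched == set(pattern):
            return GenotypeCall(genotype=geno, evidence=obs, alleles=ALLELE_PAIRS[geno])
    raise UncallableError(f"fragment pattern {sorted(matched)} is not a canonical genotype pattern")


@dataclass(frozen=True)
class AlleleStats:
    counts: dict[str, int]
    proportions: dict[str, float]
    freq_c: float
    freq_t: float

    @property
    def maf(self) -> float:
        """Minor allele frequency (the T allele at this locus; generic min otherwise)."""
        return min(self.freq_c, self.freq_t)


def genotype_frequencies(calls) -> AlleleStats:
    """Cohort genotype counts/proportions and allele frequencies.

    ``calls`` may be GenotypeCall objects or plain CC/CT/TT labels.
    f(T) = p(TT) + p(CT)/2 and f(C) = 1 - f(T).
    """
    labels = [c.genotype if isinstance(c, GenotypeCall) else str(c) for c in calls]
    if not labels:
        raise ValueError("no genotype calls supplied")
    bad = sorted(set(labels) - set(GENOTYPES))
    if bad:
        raise ValueError(f"unknown genotype label(s): {bad}")
    counts = {g: labels.count(g) for g in GENOTYPES}
    n = len(labels)
    props = {g: counts[g] / n for g in GENOTYPES}
    freq_t = props["TT"] + props["CT"] / 2
    return AlleleStats(counts=counts, proportions=props, freq_c=1 - freq_t, freq_t=freq_t)


def allele_frequencies_from_proportions(p_cc: float, p_ct: float, p_tt: float) -> tuple[float, float]:
    """(f(C), f(T)) from genotype proportions (e.g. reported percentages / 100)."""
    total = p_cc + p_ct + p_tt
    f_t = (p_tt + p_ct / 2) / total
    return 1 - f_t, f_t


def hwe_exact_test(n_cc: int, n_ct: int, n_tt: int) -> float:
    """Exact Hardy-Weinberg equilibrium test p-value.

    Enumerates every heterozygote count compatible with the observed
    allele counts and sums the conditional probabilities of all
    configurations no more probable than the observed one (the standard
    exact HWE test).  Included as a QC aid.
    """
    for c in (n_cc, n_ct, n_tt):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n_cc, n_ct, n_tt = int(n_cc), int(n_ct), int(n_tt)
    n = n_cc + n_ct + n_tt
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_rare = 2 * min(n_cc, n_tt) + n_ct  # rare-allele copies
    # log P(n_het | allele counts), up to a constant shared by all configs
    def log_prob(het: int) -> float:
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        return (
            het * log(2)
            - lgamma(het + 1)
            - lgamma(rare_hom + 1)
            - lgamma(common_hom + 1)
        )

    feasible = [h for h in range(n_rare % 2, n_rare + 1, 2) if (n - h - (n_rare - h) // 2) >= 0]
    logs = np.array([log_prob(h) for h in feasible])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[feasible.index(n_ct)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def call_cohort_genotypes(cohort: pd.DataFrame, tolerance: float = 10.0) -> pd.Series:
    """Resolve a genotype label per subject from the cohort frame.

    Uses the ``genotype`` column where present; otherwise parses the
    ``rflp_fragments`` column (';'-separated bp lengths) through
    :func:`call_genotype`.  Subjects with neither source are left missing.
    """
    out = pd.Series(pd.NA, index=cohort.index, dtype="object")
    if "genotype" in cohort.columns:
        labels = cohort["genotype"]
        ok = labels.isin(GENOTYPES)
        out[ok] = labels[ok]
    if "rflp_fragments" in cohort.columns:
        todo = out.isna() & cohort["rflp_fragments"].notna()
        for i in cohort.index[todo]:
            frags = [float(x) for x in str(cohort.at[i, "rflp_fragments"]).split(";") if x.strip()]
            out.at[i] = call_genotype(frags, tolerance=tolerance).genotype
    return out
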