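"""NAT2 star alleles: definitions, EM haplotype frequencies, diplotype calls.

A *star allele* is a named NAT2 haplotype defined by signature SNVs:
*4 is the all-reference haplotype, while *5, *6 and *7 each carry exactly
one signature variant (c.341T>C / rs1801280, c.590G>A / rs1799930 and
c.857G>A / rs1799931 respectively).  Unphased diploid genotypes over the
signature sites are resolved into diplotypes (unordered allele pairs) by
maximum-likelihood phasing against haplotype frequencies estimated with a
standard multilocus EM.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    CompoundHaplotypeError,
    DefinitionError,
    UnknownSiteError,
)

logger = logging.getLogger(__name__)

REFERENCE_ALLELE = "*4"

#: rsid, cDNA change, ref, alt, defined allele, GRCh38 position on chr8.
_NAT2_BUILTIN = (
    ("rs1801280", "c.341T>C", "T", "C", "*5", "8", 18400344),
    ("rs1799930", "c.590G>A", "G", "A", "*6", "8", 18400593),
    ("rs1799931", "c.857G>A", "G", "A", "*7", "8", 18400860),
)


@dataclass(frozen=True)
class SignatureVariant:
    """A single-nucleotide variant whose presence defines one star allele."""

    rsid: str
    cdna_change: str
    ref_base: str
    alt_base: str
    defines_allele: str
    chrom: str | None = None
    pos: int | None = None


@dataclass(frozen=True)
class StarAllele:
    """A named haplotype over the signature sites (empty set for *4)."""

    name: str
    variant_rsids: frozenset = frozenset()


def allele_sort_key(name: str) -> tuple:
    """Sort star alleles numerically: *4 < *5 < *6 < *7 < *14."""
    m = re.fullmatch(r"\*(\d+)([A-Za-z]*)", name)
    if m:
        return (0, int(m.group(1)), m.group(2))
    return (1, name)


def canonical_label(allele_a: str, allele_b: str) -> str:
    """Canonical unordered diplotype label, e.g. ``*4/*6`` (never ``*6/*4``)."""
    a, b = sorted((allele_a, allele_b), key=allele_sort_key)
    return f"{a}/{b}"


class AlleleDefinitionSet:
    """A consistent set of star alleles and their signature variants.

    The reference allele (*4) is synthesized as the all-reference haplotype;
    every variant defines exactly one named allele carrying exactly that one
    variant.  Haplotypes are represented as 0/1 patterns over the signature
    sites in definition order.
    """

    def __init__(self, variants: Sequence[SignatureVariant],
                 reference_name: str = REFERENCE_ALLELE):
        if not variants:
            raise DefinitionError("no signature variants")
        rsids = [v.rsid for v in variants]
        dup = [r for r, c in Counter(rsids).items() if c > 1]
        if dup:
            raise DefinitionError(f"duplicate rsid(s): {', '.join(dup)}")
        per_allele = Counter(v.defines_allele for v in variants)
        multi = [a for a, c in per_allele.items() if c > 1]
        if multi:
            raise DefinitionError(
                "multiple variants defining one allele are unsupported: "
                + ", ".join(multi)
            )
        if reference_name in per_allele:
            raise DefinitionError(
                f"reference allele {reference_name} must not carry a variant")
        self.variants: tuple[SignatureVariant, ...] = tuple(variants)
        self.reference_name = reference_name
        self.alleles: dict[str, StarAllele] = {
            reference_name: StarAllele(reference_name)
        }
        for v in self.variants:
            self.alleles[v.defines_allele] = StarAllele(
                v.defines_allele, frozenset({v.rsid}))

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(v.rsid for v in self.variants)

    @property
    def allele_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.alleles, key=allele_sort_key))

    def variant(self, rsid: str) -> SignatureVariant:
        for v in self.variants:
            if v.rsid == rsid:
                return v
        raise UnknownSiteError(f"unknown signature site {rsid}")

    def pattern_allele(self, pattern: Sequence[int]) -> str | None:
        """Star-allele name for a 0/1 haplotype pattern; None if compound."""
        carried = [v for v, p in zip(self.variants, pattern) if p]
        if not carried:
            return self.reference_name
        if len(carried) == 1:
            return carried[0].defines_allele
        return None

    def allele_pattern(self, name: str) -> tuple[int, ...]:
        """0/1 pattern over the signature sites for a named allele."""
        if name not in self.alleles:
            raise DefinitionError(f"unknown allele {name}")
        carried = self.alleles[name].variant_rsids
        return tuple(int(v.rsid in carried) for v in self.variants)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"AlleleDefinitionSet({', '.join(self.allele_names)}; "
                f"sites={', '.join(self.sites)})")


def load_allele_definitions(source: str | Path = "NAT2") -> AlleleDefinitionSet:
    """Load star-allele definitions from the built-in set or a TSV file.

    The built-in ``"NAT2"`` set ships the three signature sites defining
    *5, *6 and *7 (plus the implicit *4).  A TSV must have columns
    ``rsid``, ``ref``, ``alt``, ``allele`` and may add ``cdna``, ``chrom``,
    ``pos``.
    """
    if isinstance(source, str) and source.upper() == "NAT2":
        variants = [SignatureVariant(*row) for row in _NAT2_BUILTIN]
        return AlleleDefinitionSet(variants)
    path = Path(source)
    rows: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"rsid", "ref", "alt", "allele"}
        missing = required - set(header)
        if missing:
            raise DefinitionError(
                f"definition table missing column(s): {', '.join(sorted(missing))}")
        for line in fh:
            if line.strip():
                rows.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    if not rows:
        raise DefinitionError("no signature variants")
    variants = [
        SignatureVariant(
            rsid=r["rsid"],
            cdna_change=r.get("cdna", ""),
            ref_base=r["ref"],
            alt_base=r["alt"],
            defines_allele=r["allele"],
            chrom=r.get("chrom"),
            pos=int(r["pos"]) if r.get("pos") else None,
        )
        for r in rows
    ]
    return AlleleDefinitionSet(variants)


@dataclass
class GenotypeCall:
    """Unphased dosages (count of alt alleles, 0/1/2) per signature rsID."""

    individual_id: str
    dosages: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = {r: d for r, d in self.dosages.items() if d not in (0, 1, 2)}
        if bad:
            raise ValueError(
                f"{self.individual_id}: dosages must be 0, 1 or 2; got {bad}")


@dataclass(frozen=True)
class Diplotype:
    """An unordered pair of star alleles, stored in canonical order."""

    allele_a: str
    allele_b: str
    ambiguous: bool = False
    posterior: float = 1.0

    def __post_init__(self):
        a, b = sorted((self.allele_a, self.allele_b), key=allele_sort_key)
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)
        if not 0.0 <= self.posterior <= 1.0 + 1e-12:
            raise ValueError(f"posterior {self.posterior} outside [0, 1]")

    @property
    def label(self) -> str:
        return f"{self.allele_a}/{self.allele_b}"

    @classmethod
    def from_label(cls, label: str, **kw) -> "Diplotype":
        a, b = label.split("/")
        return cls(a, b, **kw)


@dataclass
class HaplotypeFrequencySet:
    """EM-estimated haplotype pattern frequencies over the signature sites."""

    sites: tuple
    frequencies: dict  # pattern tuple -> frequency
    log_likelihood: float
    iterations: int
    ll_trace: tuple = ()
    excluded: tuple = ()

    def __post_init__(self):
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total!r}, not 1")

    def frequency(self, pattern: Sequence[int]) -> float:
        return self.frequencies.get(tuple(pattern), 0.0)

    def allele_frequencies(self, definitions: AlleleDefinitionSet) -> dict:
        """Frequencies aggregated to named alleles (compounds keyed by pattern)."""
        out: dict[str, float] = {}
        for pattern, f in self.frequencies.items():
            name = definitions.pattern_allele(pattern) or "+".join(
                v.rsid for v, p in zip(definitions.variants, pattern) if p)
            out[name] = out.get(name, 0.0) + f
        return out


def _compatible_pairs(dosages: tuple, n_sites: int):
    """Unordered haplotype-pattern pairs consistent with a dosage vector.

    ``None`` at a site means the dosage is unobserved, leaving both
    haplotypes unconstrained there.
    """
    per_site: list[list[tuple[int, int]]] = []
    for d in dosages:
        if d is None:
            per_site.append([(0, 0), (0, 1), (1, 0), (1, 1)])
        elif d == 0:
            per_site.append([(0, 0)])
        elif d == 1:
            per_site.append([(0, 1), (1, 0)])
        else:
            per_site.append([(1, 1)])
    seen = set()
    for combo in itertools.product(*per_site):
        h1 = tuple(c[0] for c in combo)
        h2 = tuple(c[1] for c in combo)
        pair = (h1, h2) if h1 <= h2 else (h2, h1)
        if pair not in seen:
            seen.add(pair)
            yield pair


def em_haplotype_frequencies(
    calls: Sequence[GenotypeCall],
    sites: Sequence[str] | None = None,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> HaplotypeFrequencySet:
    """Estimate haplotype frequencies from unphased genotypes by EM.

    All ``2**len(sites)`` haplotype patterns are enumerated (so at most 8
    sites are supported), frequencies are initialized uniformly, and the
    E/M steps iterate until the log-likelihood gain drops below ``tol`` or
    ``max_iter`` is reached.  The procedure is fully deterministic.

    Sites with no observed dosage in any individual are dropped with a
    warning; individuals missing a dosage at a retained site are excluded
    (and reported in ``excluded``) rather than imputed.
    """
    if not calls:
        raise ValueError("need at least one individual")
    if sites is None:
        sites = sorted({r for c in calls for r in c.dosages})
    sites = tuple(sites)
    observed = [s for s in sites if any(s in c.dosages for c in calls)]
    dropped = set(sites) - set(observed)
    if dropped:
        logger.warning("dropping site(s) with no observed genotypes: %s",
                       ", ".join(sorted(dropped)))
    sites = tuple(observed)
    if not sites:
        raise ValueError("no sites with observed genotypes")
    if len(sites) > 8:
        raise ValueError(f"{len(sites)} sites exceeds the supported maximum of 8")

    excluded, usable = [], []
    for c in calls:
        if all(s in c.dosages for s in sites):
            usable.append(tuple(c.dosages[s] for s in sites))
        else:
            excluded.append(c.individual_id)
    if excluded:
        logger.warning("excluded %d individual(s) with missing dosages: %s",
                       len(excluded), ", ".join(excluded[:10]))
    if not usable:
        raise ValueError("no individuals with complete dosages")

    geno_counts = Counter(usable)
    pair_table = {g: list(_compatible_pairs(g, len(sites)))
                  for g in geno_counts}

    k = len(sites)
    patterns = list(itertools.product((0, 1), repeat=k))
    freq = {p: 1.0 / len(patterns) for p in patterns}
    n = sum(geno_counts.values())

    ll_trace: list[float] = []
    prev_ll = -math.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        counts = {p: 0.0 for p in patterns}
        ll = 0.0
        for g, c in geno_counts.items():
            pairs = pair_table[g]
            weights = [
                freq[h1] * freq[h2] * (1.0 if h1 == h2 else 2.0)
                for h1, h2 in pairs
            ]
            total = sum(weights)
            if total <= 0.0:
                # all supporting haplotypes currently at frequency zero;
                # spread expectation uniformly to keep the E-step defined
                weights = [1.0] * len(pairs)
                total = float(len(pairs))
            else:
                ll += c * math.log(total)
            for (h1, h2), w in zip(pairs, weights):
                share = c * w / total
                counts[h1] += share
                counts[h2] += share
        if ll < prev_ll - 1e-9:
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        ll_trace.append(ll)
        freq = {p: counts[p] / (2.0 * n) for p in patterns}
        if ll - prev_ll < tol and iterations > 1:
            break
        prev_ll = ll

    # renormalize away floating-point drift
    total = sum(freq.values())
    freq = {p: f / total for p, f in freq.items()}
    return HaplotypeFrequencySet(
        sites=sites,
        frequencies=freq,
        log_likelihood=ll_trace[-1],
        iterations=iterations,
        ll_trace=tuple(ll_trace),
        excluded=tuple(excluded),
    )


def call_diplotype(
    call: GenotypeCall,
    freqs: HaplotypeFrequencySet,
    definitions: AlleleDefinitionSet,
) -> Diplotype:
    """Resolve one individual's dosages into a star-allele diplotype.

    All phase configurations consistent with the observed dosages are
    enumerated; the configuration with the maximum product of haplotype
    frequencies wins (ties broken by lexicographic order of the canonical
    label).  ``posterior`` is the winning configuration's share of the
    total likelihood and ``ambiguous`` is set when it is below 1.

    Raises :class:`CompoundHaplotypeError` if the chosen configuration
    contains a haplotype carrying two or more signature variants: the
    supported allele universe is exactly {*4, *5, *6, *7}.
    """
    unknown = set(call.dosages) - set(freqs.sites)
    if unknown:
        raise UnknownSiteError(
            f"{call.individual_id}: dosage at unknown rsid(s) "
            + ", ".join(sorted(unknown)))
    if not any(s in call.dosages for s in freqs.sites):
        raise ValueError(f"{call.individual_id}: no dosage at any signature site")

    dosages = tuple(call.dosages.get(s) for s in freqs.sites)
    configs = list(_compatible_pairs(dosages, len(freqs.sites)))
    weights = [
        freqs.frequency(h1) * freqs.frequency(h2) * (1.0 if h1 == h2 else 2.0)
        for h1, h2 in configs
    ]
    total = sum(weights)
    if total <= 0.0:
        # no frequency support anywhere (e.g. freqs from a disjoint cohort):
        # fall back to a uniform prior over consistent configurations
        weights = [1.0] * len(configs)
        total = float(len(configs))

    def _config_label(cfg) -> str:
        names = []
        for h in cfg:
            name = definitions.pattern_allele(h)
            names.append(name if name is not None else "zz" + str(h))
        return canonical_label(*names) if len(names) == 2 else str(cfg)

    order = sorted(
        range(len(configs)),
        key=lambda i: (-weights[i], _config_label(configs[i])),
    )
    best = order[0]
    h1, h2 = configs[best]
    posterior = weights[best] / total
    name1 = definitions.pattern_allele(h1)
    name2 = definitions.pattern_allele(h2)
    for name, h in ((name1, h1), (name2, h2)):
        if name is None:
            carried = [v.rsid for v, p in zip(definitions.variants, h) if p]
            raise CompoundHaplotypeError(
                f"{call.individual_id}: most likely phase places "
                f"{' and '.join(carried)} on one haplotype; compound alleles "
                "are outside the supported universe {*4, *5, *6, *7}")
    return Diplotype(name1, name2,
                     ambiguous=posterior < 1.0 - 1e-9,
                     posterior=min(posterior, 1.0))


def estimate_allele_frequencies(
    diplotypes: Sequence[Diplotype],
) -> dict:
    """Gamete-counting allele frequencies from called diplotypes."""
    if not diplotypes:
        raise ValueError("empty diplotype list")
    counts: Counter = Counter()
    for d in diplotypes:
        counts[d.allele_a] += 1
        counts[d.allele_b] += 1
    n = 2 * len(diplotypes)
    return {a: counts[a] / n for a in sorted(counts, key=allele_sort_key)}
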