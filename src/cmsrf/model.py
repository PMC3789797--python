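"""Cytonuclear inheritance calculus for a CMS–restorer (Rf) system.

The model: a maternally inherited cytoplasm either carries a male-sterility
factor (CMS) or not.  A single nuclear restorer locus segregates a dominant
restorer allele ``R`` and a nonrestorer allele ``m``.  A plant with CMS
cytoplasm is hermaphrodite (H) if it carries at least one ``R``; an ``mm``
plant escapes sterility only through partial restoration (penetrance ``r``),
modelled as an independent Bernoulli per individual.  Heterozygous parents may
transmit the nonrestorer allele with probability ``tau != 0.5`` (transmission
ratio distortion); ``T_R = 1 - tau`` is the restorer transmission.

Chained crosses (F2, pseudobackcross generations BC1..BC3) are expressed as
:class:`CrossChain` objects.  Because the penetrance of an ``mm`` offspring may
differ depending on whether its mother was genotypically restored (``r_R``) or
an unrestored phenocopy (``r_N``), the chain propagation tracks the joint
distribution of (offspring genotype, mother carried R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

GENOTYPES = ("RR", "Rm", "mm")
_SUM_TOL = 1e-12


class InvalidDistributionError(ValueError):
    """A genotype/gamete distribution is negative or does not sum to 1."""


class ImpossibleConditionError(ValueError):
    """Conditioning on a phenotype that has probability 0 under the model."""


@dataclass(frozen=True)
class CytoplasmType:
    """A maternally inherited cytoplasm, e.g. ``Sp`` (CMS) or ``Ma`` (normal)."""

    label: str
    carries_cms: bool

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("cytoplasm label must be nonempty")


#: The two cytoplasms of the main crossing family plus the CMS-free variant.
SP_CMS = CytoplasmType("Sp", carries_cms=True)
MA = CytoplasmType("Ma", carries_cms=False)
SP4 = CytoplasmType("Sp4", carries_cms=False)


@dataclass(frozen=True)
class RfGenotype:
    """An ordered pair of restorer-locus alleles, each ``R`` or ``m``.

    Alleles may carry an origin tag (population label) after a colon, e.g.
    ``"R:Sp"``; only the leading letter enters the genotype class.
    """

    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError("RfGenotype requires exactly two alleles")
        for a in self.alleles:
            if a.split(":")[0] not in ("R", "m"):
                raise ValueError(f"allele must be R or m, got {a!r}")

    @property
    def genotype_class(self) -> str:
        """Unordered class: ``RR``, ``Rm`` or ``mm``."""
        letters = sorted(a.split(":")[0] for a in self.alleles)
        return {"Rm": "Rm", "RR": "RR", "mm": "mm"}["".join(letters)]

    @property
    def carries_restorer(self) -> bool:
        return "R" in self.genotype_class

    @classmethod
    def from_class(cls, g: str) -> "RfGenotype":
        if g not in GENOTYPES:
            raise ValueError(f"unknown genotype class {g!r}")
        return cls(tuple(g))  # type: ignore[arg-type]


class GenotypeDist(Mapping[str, float]):
    """A probability distribution over the genotype classes ``RR, Rm, mm``."""

    __slots__ = ("_p",)

    def __init__(self, probabilities: Mapping[str, float]):
        p = {g: float(probabilities.get(g, 0.0)) for g in GENOTYPES}
        extra = set(probabilities) - set(GENOTYPES)
        if extra:
            raise InvalidDistributionError(f"unknown genotype classes: {sorted(extra)}")
        if any(v < -_SUM_TOL for v in p.values()):
            raise InvalidDistributionError("negative probability")
        total = sum(p.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidDistributionError(f"probabilities sum to {total}, not 1")
        # renormalise away float dust so downstream sums stay within 1e-12
        self._p = {g: max(v, 0.0) / total for g, v in p.items()}

    @classmethod
    def point(cls, genotype: str) -> "GenotypeDist":
        return cls({genotype: 1.0})

    def __getitem__(self, g: str) -> float:
        return self._p[g]

    def __iter__(self):
        return iter(self._p)

    def __len__(self) -> int:
        return len(self._p)

    def __repr__(self) -> str:
        inner = ", ".join(f"{g}: {v:.6g}" for g, v in self._p.items() if v)
        return f"GenotypeDist({{{inner}}})"

    def isclose(self, other: "GenotypeDist", tol: float = 1e-9) -> bool:
        return all(abs(self[g] - other[g]) <= tol for g in GENOTYPES)


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of the one-locus cytonuclear model.

    tau
        Probability that a heterozygous parent transmits the nonrestorer
        allele ``m`` (``T_R = 1 - tau`` is restorer transmission).  Applied to
        both sexes unless ``tau_f`` is set.
    r_r
        Restoration probability (penetrance of fertility) for an ``mm``
        offspring of a genotypically restored (R-carrying) mother.
    r_n
        Same, for an ``mm`` offspring of a nonrestored mother.
    dominant
        Restorer acts dominantly (a single ``R`` suffices); the only mode
        used by the study's models.
    tau_f
        Optional separate paternal transmission; ``None`` means equal to tau.
    """

    tau: float = 0.5
    r_r: float = 0.4
    r_n: float = 0.4
    dominant: bool = True
    tau_f: float | None = None

    def __post_init__(self) -> None:
        for name in ("tau", "r_r", "r_n"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.tau_f is not None and not 0.0 <= self.tau_f <= 1.0:
            raise ValueError(f"tau_f={self.tau_f} outside [0, 1]")
        if not self.dominant:
            raise NotImplementedError("only the dominant-restorer model is implemented")

    @property
    def tau_m(self) -> float:
        return self.tau

    @property
    def paternal_tau(self) -> float:
        return self.tau if self.tau_f is None else self.tau_f

    def with_restoration(self, r: float) -> "ModelParams":
        return replace(self, r_r=r, r_n=r)


def gamete_dist(parent: RfGenotype | str, tau: float) -> dict[str, float]:
    """Gamete distribution of a parent under transmission ratio distortion.

    A heterozygote transmits ``m`` with probability ``tau``; homozygotes
    transmit their sole allele with certainty.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau={tau} outside [0, 1]")
    g = parent.genotype_class if isinstance(parent, RfGenotype) else parent
    if g == "RR":
        return {"R": 1.0, "m": 0.0}
    if g == "mm":
        return {"R": 0.0, "m": 1.0}
    if g == "Rm":
        return {"R": 1.0 - tau, "m": tau}
    raise ValueError(f"unknown genotype {g!r}")


def _combine(a_m: str, a_p: str) -> str:
    return {"RR": "RR", "Rm": "Rm", "mR": "Rm", "mm": "mm"}[a_m + a_p]


def progeny_rf_dist(
    mother: GenotypeDist | str,
    father: GenotypeDist | str,
    tau_m: float,
    tau_f: float | None = None,
) -> GenotypeDist:
    """Offspring genotype distribution: convolution of parental gamete draws."""
    if tau_f is None:
        tau_f = tau_m
    mdist = GenotypeDist.point(mother) if isinstance(mother, str) else mother
    fdist = GenotypeDist.point(father) if isinstance(father, str) else father
    out = {g: 0.0 for g in GENOTYPES}
    for gm, pm in mdist.items():
        if pm == 0.0:
            continue
        gam_m = gamete_dist(gm, tau_m)
        for gf, pf in fdist.items():
            if pf == 0.0:
                continue
            gam_f = gamete_dist(gf, tau_f)
            for am, qa in gam_m.items():
                for af, qb in gam_f.items():
                    out[_combine(am, af)] += pm * pf * qa * qb
    return GenotypeDist(out)


def phenotype_prob(
    genotype: RfGenotype | str,
    cyt: CytoplasmType,
    restoration: float,
) -> float:
    """P(hermaphrodite) for a plant of the given genotype and cytoplasm.

    Without CMS cytoplasm the plant is always fertile; with CMS, a dominant
    restorer guarantees fertility and an ``mm`` plant is fertile with the
    penetrance ``restoration``.
    """
    if not 0.0 <= restoration <= 1.0:
        raise ValueError(f"restoration={restoration} outside [0, 1]")
    if not cyt.carries_cms:
        return 1.0
    g = genotype.genotype_class if isinstance(genotype, RfGenotype) else genotype
    if g not in GENOTYPES:
        raise ValueError(f"unknown genotype {g!r}")
    return 1.0 if "R" in g else restoration


def condition_on_phenotype(
    dist: GenotypeDist,
    phenotype: str,
    cyt: CytoplasmType,
    restoration: float,
) -> GenotypeDist:
    """Bayes posterior over genotypes given an observed H/MS phenotype.

    For phenotype ``H`` the posterior mass on R-carriers is the quantity the
    study calls F_r (frequency of genotypically restored among hermaphrodites).
    """
    if phenotype not in ("H", "MS"):
        raise ValueError(f"phenotype must be 'H' or 'MS', got {phenotype!r}")
    weights = {}
    for g, p in dist.items():
        ph = phenotype_prob(g, cyt, restoration)
        weights[g] = p * (ph if phenotype == "H" else 1.0 - ph)
    total = sum(weights.values())
    if total <= 0.0:
        raise ImpossibleConditionError(
            f"phenotype {phenotype} has probability 0 under this distribution"
        )
    return GenotypeDist({g: w / total for g, w in weights.items()})


# ---------------------------------------------------------------------------
# Cross chains


@dataclass(frozen=True)
class CrossStep:
    """One cross in a chain.

    ``mother`` is an explicit :class:`GenotypeDist` (or genotype class string)
    for the first step, or the sentinel ``"previous"`` meaning mothers are
    drawn from the previous step's progeny.  ``condition`` optionally restricts
    those mothers to phenotype ``"H"`` or ``"MS"`` before they are crossed.
    """

    mother: GenotypeDist | str
    father: GenotypeDist | str
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in (None, "H", "MS"):
            raise ValueError(f"condition must be None, 'H' or 'MS', got {self.condition!r}")


@dataclass(frozen=True)
class CrossChain:
    """An ordered sequence of crosses sharing one maternal cytoplasm lineage."""

    cytoplasm: CytoplasmType
    steps: tuple[CrossStep, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("chain needs at least one step")
        for i, s in enumerate(self.steps):
            if i == 0 and s.mother == "previous":
                raise ValueError("first step needs an explicit mother distribution")
            if i > 0 and s.mother != "previous":
                raise ValueError("later steps must draw mothers from the previous progeny")


def _as_dist(x: GenotypeDist | str) -> GenotypeDist:
    return GenotypeDist.point(x) if isinstance(x, str) else x


# joint state: {(genotype, mother_carried_R: bool): probability}
_State = dict[tuple[str, bool], float]


def _phenotype_prob_state(g: str, mc: bool, cyt: CytoplasmType, params: ModelParams) -> float:
    r = params.r_r if mc else params.r_n
    return phenotype_prob(g, cyt, r)


def _condition_state(state: _State, phenotype: str, cyt: CytoplasmType, params: ModelParams) -> _State:
    out: _State = {}
    for (g, mc), p in state.items():
        ph = _phenotype_prob_state(g, mc, cyt, params)
        w = p * (ph if phenotype == "H" else 1.0 - ph)
        if w > 0.0:
            out[(g, mc)] = w
    total = sum(out.values())
    if total <= 0.0:
        raise ImpossibleConditionError(
            f"conditioning on {phenotype} is impossible mid-chain"
        )
    return {k: v / total for k, v in out.items()}


def chain_progeny_state(chain: CrossChain, params: ModelParams) -> _State:
    """Propagate the joint (genotype, mother-carried-R) distribution.

    Explicit first-step mothers are treated as having unrestored mothers
    themselves (only relevant if the chain conditions on their phenotype,
    which the study's designs never do).
    """
    state: _State | None = None
    for step in chain.steps:
        if step.mother == "previous":
            assert state is not None
            mothers = state
        else:
            mothers = {(g, False): p for g, p in _as_dist(step.mother).items() if p > 0.0}
        if step.condition is not None:
            mothers = _condition_state(mothers, step.condition, chain.cytoplasm, params)
        fdist = _as_dist(step.father)
        new: _State = {}
        for (gm, _mc), pm in mothers.items():
            gam_m = gamete_dist(gm, params.tau_m)
            child_mc = "R" in gm
            for gf, pf in fdist.items():
                if pf == 0.0:
                    continue
                gam_f = gamete_dist(gf, params.paternal_tau)
                for am, qa in gam_m.items():
                    if qa == 0.0:
                        continue
                    for af, qb in gam_f.items():
                        if qb == 0.0:
                            continue
                        key = (_combine(am, af), child_mc)
                        new[key] = new.get(key, 0.0) + pm * pf * qa * qb
        state = new
    assert state is not None
    total = sum(state.values())
    assert abs(total - 1.0) < 1e-9
    return {k: v / total for k, v in state.items()}


def chain_h_prob(chain: CrossChain, params: ModelParams) -> float:
    """P(hermaphrodite) among the final progeny of a cross chain."""
    state = chain_progeny_state(chain, params)
    return sum(
        p * _phenotype_prob_state(g, mc, chain.cytoplasm, params)
        for (g, mc), p in state.items()
    )


def chain_genotype_dist(chain: CrossChain, params: ModelParams) -> GenotypeDist:
    """Marginal genotype distribution of the final progeny."""
    state = chain_progeny_state(chain, params)
    out = {g: 0.0 for g in GENOTYPES}
    for (g, _mc), p in state.items():
        out[g] += p
    return GenotypeDist(out)


# -- standard chains of the study design ------------------------------------


def f2_chain(cyt: CytoplasmType = SP_CMS) -> CrossChain:
    """F2: heterozygous F1 mother x heterozygous F1 father."""
    return CrossChain(cyt, (CrossStep("Rm", "Rm"),), label="F2")


def bc1_chain(cyt: CytoplasmType = SP_CMS) -> CrossChain:
    """BC1 pseudobackcross: F1 (Rm) mother x recurrent nonrestorer (mm) father."""
    return CrossChain(cyt, (CrossStep("Rm", "mm"),), label="BC1")


def bc2_chain(mother_phenotype: str = "H", cyt: CytoplasmType = SP_CMS) -> CrossChain:
    """BC2: BC1 progeny, conditioned on maternal phenotype, x mm father."""
    return CrossChain(
        cyt,
        (CrossStep("Rm", "mm"), CrossStep("previous", "mm", condition=mother_phenotype)),
        label=f"BC2({mother_phenotype})",
    )


def bc3_chain(
    bc1_phenotype: str = "H", bc2_phenotype: str = "H", cyt: CytoplasmType = SP_CMS
) -> CrossChain:
    """BC3: two successive phenotype-conditioned pseudobackcross steps."""
    return CrossChain(
        cyt,
        (
            CrossStep("Rm", "mm"),
            CrossStep("previous", "mm", condition=bc1_phenotype),
            CrossStep("previous", "mm", condition=bc2_phenotype),
        ),
        label=f"BC3({bc1_phenotype},{bc2_phenotype})",
    )


STANDARD_CHAINS = {
    "F2": f2_chain,
    "BC1": bc1_chain,
    "BC2(H)": lambda: bc2_chain("H"),
    "BC2(MS)": lambda: bc2_chain("MS"),
    "BC3(H)": lambda: bc3_chain("H", "H"),
    "BC3(MS)": lambda: bc3_chain("H", "MS"),
}


# -- multi-locus extension (classical ratios only) ---------------------------


def multi_locus_h_prob(
    loci: Sequence[tuple[GenotypeDist | str, str]],
    cyt: CytoplasmType = SP_CMS,
) -> float:
    """P(H) with several independently segregating restorer loci.

    Each locus is (genotype distribution, action) with action ``"dominant"``
    (any R restores) or ``"recessive"`` (only RR restores).  A plant is MS only
    if every locus fails to restore; used to express textbook ratios such as
    the 13:3 F2 ratio of a dominant plus a recessive restorer.  Not fitted.
    """
    if not cyt.carries_cms:
        return 1.0
    p_ms = 1.0
    for dist, action in loci:
        d = _as_dist(dist)
        if action == "dominant":
            p_fail = d["mm"]
        elif action == "recessive":
            p_fail = 1.0 - d["RR"]
        else:
            raise ValueError(f"unknown restorer action {action!r}")
        p_ms *= p_fail
    return 1.0 - p_ms
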