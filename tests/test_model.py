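"""Unit and property tests of the cytonuclear inheritance calculus."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmsrf.model import (
    GENOTYPES,
    MA,
    SP4,
    SP_CMS,
    CrossChain,
    CrossStep,
    CytoplasmType,
    GenotypeDist,
    ImpossibleConditionError,
    InvalidDistributionError,
    ModelParams,
    RfGenotype,
    bc1_chain,
    bc2_chain,
    bc3_chain,
    chain_genotype_dist,
    chain_h_prob,
    condition_on_phenotype,
    f2_chain,
    gamete_dist,
    multi_locus_h_prob,
    phenotype_prob,
    progeny_rf_dist,
)

TAU = 0.575


# ---------------------------------------------------------------------------
# Independent enumeration oracle: expands every gamete combination and every
# Bernoulli restoration outcome into explicit paths, without reusing the
# distribution propagation of the implementation.


def oracle_paths(chain, params):
    """Yield (prob, genotype, mother_carries_R) for the final progeny."""
    tau_m, tau_f = params.tau, params.paternal_tau

    def gametes(genotype, tau):
        if genotype == "RR":
            return [("R", 1.0)]
        if genotype == "mm":
            return [("m", 1.0)]
        return [("R", 1.0 - tau), ("m", tau)]

    def p_h(genotype, mother_carrier):
        if not chain.cytoplasm.carries_cms:
            return 1.0
        if "R" in genotype:
            return 1.0
        return params.r_r if mother_carrier else params.r_n

    paths = None
    for step in chain.steps:
        if step.mother == "previous":
            mothers = paths
        else:
            md = GenotypeDist.point(step.mother) if isinstance(step.mother, str) else step.mother
            mothers = [(p, g, False) for g, p in md.items() if p > 0]
        if step.condition is not None:
            selected = []
            for p, g, mc in mothers:
                w = p_h(g, mc) if step.condition == "H" else 1.0 - p_h(g, mc)
                if p * w > 0:
                    selected.append((p * w, g, mc))
            z = sum(p for p, _, _ in selected)
            if z == 0.0:
                raise ZeroDivisionError("conditioning impossible")
            mothers = [(p / z, g, mc) for p, g, mc in selected]
        fd = GenotypeDist.point(step.father) if isinstance(step.father, str) else step.father
        new = []
        for p, g, _mc in mothers:
            for gf, pf in fd.items():
                if pf == 0:
                    continue
                for am, qa in gametes(g, tau_m):
                    for af, qb in gametes(gf, tau_f):
                        geno = "".join(sorted(am + af, key="Rm".index))
                        new.append((p * pf * qa * qb, geno, "R" in g))
        paths = new
    return paths, p_h


def oracle_chain_h(chain, params):
    paths, p_h = oracle_paths(chain, params)
    return sum(p * p_h(g, mc) for p, g, mc in paths)


# ---------------------------------------------------------------------------


class TestGameteDist:
    @pytest.mark.parametrize(
        "genotype,tau,expected",
        [
            ("Rm", TAU, {"m": 0.575, "R": 0.425}),
            ("RR", 0.99, {"R": 1.0, "m": 0.0}),
            ("mm", 0.1, {"R": 0.0, "m": 1.0}),
            ("Rm", 0.5, {"m": 0.5, "R": 0.5}),
        ],
    )
    def test_examples(self, genotype, tau, expected):
        d = gamete_dist(genotype, tau)
        assert d == pytest.approx(expected)
        assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)

    def test_tau_out_of_range(self):
        with pytest.raises(ValueError):
            gamete_dist("Rm", 1.2)

    def test_accepts_rf_genotype_with_origin_tags(self):
        g = RfGenotype(("R:Sp", "m:Ma"))
        assert g.genotype_class == "Rm"
        assert gamete_dist(g, 0.575)["m"] == pytest.approx(0.575)


class TestProgenyDist:
    def test_f2_distorted_mm(self):
        d = progeny_rf_dist("Rm", "Rm", TAU, TAU)
        assert d["mm"] == pytest.approx(0.575**2)  # 0.330625

    def test_mendelian_1_2_1(self):
        d = progeny_rf_dist("Rm", "Rm", 0.5, 0.5)
        assert dict(d) == pytest.approx({"RR": 0.25, "Rm": 0.5, "mm": 0.25})

    def test_backcross(self):
        d = progeny_rf_dist("Rm", "mm", TAU)
        assert d["Rm"] == pytest.approx(0.425)
        assert d["mm"] == pytest.approx(0.575)

    def test_invalid_distribution_rejected(self):
        with pytest.raises(InvalidDistributionError):
            GenotypeDist({"RR": 0.7, "mm": 0.7})
        with pytest.raises(InvalidDistributionError):
            GenotypeDist({"RR": -0.1, "Rm": 1.1})


class TestPhenotypeProb:
    @pytest.mark.parametrize(
        "genotype,cyt,restoration,expected",
        [
            ("mm", SP_CMS, 0.4, 0.4),
            ("Rm", SP_CMS, 0.0, 1.0),
            ("RR", SP_CMS, 0.0, 1.0),
            ("mm", SP4, 0.0, 1.0),
            ("mm", MA, 0.0, 1.0),
        ],
    )
    def test_examples(self, genotype, cyt, restoration, expected):
        assert phenotype_prob(genotype, cyt, restoration) == expected


class TestConditionOnPhenotype:
    def test_posterior_is_fr(self):
        prior = GenotypeDist({"Rm": 0.425, "mm": 0.575})
        post = condition_on_phenotype(prior, "H", SP_CMS, 0.4)
        fr = 0.425 / (0.425 + 0.575 * 0.4)
        assert post["Rm"] == pytest.approx(fr, abs=1e-6)  # 0.6489
        assert post["mm"] == pytest.approx(1 - fr, abs=1e-6)

    def test_ms_with_zero_restoration_is_all_mm(self):
        prior = GenotypeDist({"RR": 0.2, "Rm": 0.5, "mm": 0.3})
        post = condition_on_phenotype(prior, "MS", SP_CMS, 0.0)
        assert post["mm"] == pytest.approx(1.0)

    def test_full_restoration_uninformative(self):
        prior = GenotypeDist({"RR": 0.1, "Rm": 0.4, "mm": 0.5})
        post = condition_on_phenotype(prior, "H", SP_CMS, 1.0)
        assert post.isclose(prior)

    def test_impossible_condition_raises(self):
        prior = GenotypeDist({"Rm": 1.0})
        with pytest.raises(ImpossibleConditionError):
            condition_on_phenotype(prior, "MS", MA, 0.0)


class TestChains:
    def test_f2_h_prob(self, params):
        assert chain_h_prob(f2_chain(), params) == pytest.approx(1 - 0.6 * 0.575**2)

    def test_bc2_h_strict_dominant_matches_tr(self):
        strict = ModelParams(tau=TAU, r_r=0.0, r_n=0.0)
        assert chain_h_prob(bc2_chain("H"), strict) == pytest.approx(0.425)

    def test_bc2_h_matches_footnote_formula(self, params):
        # [F_r (T_R + (1-T_R) r_R) + (1-F_r) r_N]
        tr, rr, rn = 0.425, params.r_r, params.r_n
        fr = tr / (tr + (1 - tr) * rr)
        expected = fr * (tr + (1 - tr) * rr) + (1 - fr) * rn
        assert chain_h_prob(bc2_chain("H"), params) == pytest.approx(expected)

    def test_non_cms_cytoplasm_never_ms(self, params):
        for chain in (f2_chain(MA), bc1_chain(SP4), bc3_chain("H", "H", MA)):
            assert chain_h_prob(chain, params) == 1.0

    def test_mendelian_f2_quarter_ms(self):
        p = ModelParams(tau=0.5, r_r=0.0, r_n=0.0)
        assert chain_h_prob(f2_chain(), p) == pytest.approx(0.75)

    def test_two_locus_extension_13_3(self):
        f2 = progeny_rf_dist("Rm", "Rm", 0.5)
        p_h = multi_locus_h_prob([(f2, "dominant"), (f2, "recessive")])
        assert p_h == pytest.approx(13 / 16)

    @pytest.mark.parametrize("tau", [0.4, 0.5, 0.575, 0.7])
    @pytest.mark.parametrize("r", [0.0, 0.2, 0.4, 1.0])
    @pytest.mark.parametrize(
        "make",
        [f2_chain, bc1_chain, lambda: bc2_chain("H"), lambda: bc2_chain("MS"),
         lambda: bc3_chain("H", "H"), lambda: bc3_chain("H", "MS"),
         lambda: bc3_chain("MS", "MS")],
    )
    def test_equivalence_with_enumeration_oracle(self, make, tau, r):
        chain = make()
        p = ModelParams(tau=tau, r_r=r, r_n=min(1.0, r + 0.1))
        try:
            expected = oracle_chain_h(chain, p)
        except ZeroDivisionError:
            with pytest.raises(ImpossibleConditionError):
                chain_h_prob(chain, p)
            return
        assert chain_h_prob(chain, p) == pytest.approx(expected, abs=1e-12)

    def test_distinct_maternal_penetrance_classes(self):
        # r_R and r_N act on different chain branches of BC2(H)
        p = ModelParams(tau=TAU, r_r=0.6, r_n=0.1)
        tr = 1 - TAU
        fr = tr / (tr + TAU * p.r_r)
        expected = fr * (tr + TAU * p.r_r) + (1 - fr) * p.r_n
        assert chain_h_prob(bc2_chain("H"), p) == pytest.approx(expected)

    def test_chain_validation(self):
        with pytest.raises(ValueError):
            CrossChain(SP_CMS, ())
        with pytest.raises(ValueError):
            CrossChain(SP_CMS, (CrossStep("previous", "mm"),))
        with pytest.raises(ValueError):
            CrossStep("Rm", "mm", condition="female")


class TestProperties:
    @given(tau=st.floats(0, 1), r=st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_distributions_sum_to_one(self, tau, r):
        for chain in (f2_chain(), bc2_chain("H")):
            p = ModelParams(tau=tau, r_r=r, r_n=r)
            try:
                d = chain_genotype_dist(chain, p)
            except ImpossibleConditionError:
                continue
            assert abs(sum(d.values()) - 1.0) < 1e-12

    @given(
        r1=st.floats(0.0, 1.0), r2=st.floats(0.0, 1.0),
        tau1=st.floats(0.0, 1.0), tau2=st.floats(0.0, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_h_prob_monotone_in_restoration_and_transmission(self, r1, r2, tau1, tau2):
        r_lo, r_hi = sorted((r1, r2))
        t_lo, t_hi = sorted((tau1, tau2))
        chain = f2_chain()
        # nondecreasing in restoration
        p_lo = chain_h_prob(chain, ModelParams(tau=0.55, r_r=r_lo, r_n=r_lo))
        p_hi = chain_h_prob(chain, ModelParams(tau=0.55, r_r=r_hi, r_n=r_hi))
        assert p_hi >= p_lo - 1e-12
        # nondecreasing in restorer transmission 1 - tau
        p_lo = chain_h_prob(chain, ModelParams(tau=t_hi, r_r=0.3, r_n=0.3))
        p_hi = chain_h_prob(chain, ModelParams(tau=t_lo, r_r=0.3, r_n=0.3))
        assert p_hi >= p_lo - 1e-12


class TestTypes:
    def test_cytoplasm_label_required(self):
        with pytest.raises(ValueError):
            CytoplasmType("", True)

    def test_model_params_validation(self):
        with pytest.raises(ValueError):
            ModelParams(tau=1.5)
        with pytest.raises(ValueError):
            ModelParams(r_r=-0.2)

    def test_rf_genotype_validation(self):
        with pytest.raises(ValueError):
            RfGenotype(("R",))  # type: ignore[arg-type]
        with pytest.raises(ValueError):
            RfGenotype(("R", "x"))
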