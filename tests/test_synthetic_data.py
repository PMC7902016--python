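"""Generator determinism, planted structure, and analytic self-checks."""

from dataclasses import replace

import numpy as np
import pytest

from coldcomp.io_model import AA_ALPHABET, DIPEPTIDES, InputError
from coldcomp.composition_metrics import flexibility_pct
from coldcomp.growth_kinetics import determine_otg, fit_growth_rate
from coldcomp.synthetic_data import (
    BASE_COMPOSITION,
    PlantedGradient,
    SyntheticStudySpec,
    default_recovery_spec,
    generate_growth_curves,
    generate_proteome,
    generate_tm_table,
    group_composition,
    planted_rate,
)


def small_spec(**kw):
    defaults = dict(seed=5, proteins_per_group=40, groups=("ENZY", "RIBO"))
    defaults.update(kw)
    return SyntheticStudySpec(**defaults)


class TestDeterminism:
    def test_same_seed_identical_proteomes(self):
        a, _ = generate_proteome(small_spec(), 0)
        b, _ = generate_proteome(small_spec(), 0)
        assert [(p.protein_id, p.sequence) for p in a] == [
            (p.protein_id, p.sequence) for p in b
        ]

    def test_different_seeds_differ(self):
        a, _ = generate_proteome(small_spec(), 0)
        b, _ = generate_proteome(small_spec(seed=6), 0)
        assert a[0].sequence != b[0].sequence

    def test_same_seed_identical_curves(self):
        a = generate_growth_curves(small_spec(), 2)
        b = generate_growth_curves(small_spec(), 2)
        assert a == b

    def test_tm_table_reproducible(self):
        assert generate_tm_table(3).weight == generate_tm_table(3).weight


class TestPlantedComposition:
    def test_no_gradient_matches_base_within_3se(self):
        spec = small_spec(proteins_per_group=200, dirichlet_concentration=1e9)
        prots, _ = generate_proteome(spec, 0)
        vf_base = sum(BASE_COMPOSITION[a] for a in "EGKNQS") / sum(BASE_COMPOSITION.values()) * 100
        vals = [flexibility_pct(p)[0] for p in prots]
        n_res = sum(len(p.sequence) for p in prots)
        se = 100 * np.sqrt(vf_base / 100 * (1 - vf_base / 100) / n_res)
        assert abs(np.mean([np.average(vals, weights=[len(p.sequence) for p in prots])]) - vf_base) < 3 * se

    def test_planted_vmf_gradient_orders_organisms(self):
        spec = SyntheticStudySpec(
            seed=11,
            proteins_per_group=500,
            groups=("ENZY",),
            gradients=(PlantedGradient("ENZY", "VMf", -0.2, "OTG"),),
        )
        means = []
        for i in range(8):
            prots, _ = generate_proteome(spec, i)
            means.append(np.mean([flexibility_pct(p)[1] for p in prots]))
        r = np.corrcoef(spec.planted_otg, means)[0, 1]
        assert r < -0.9

    def test_gradient_changes_only_target_class_expectation(self):
        spec = small_spec(gradients=(PlantedGradient("ENZY", "VMf", -0.2, "OTG"),))
        p_lo = group_composition(spec, "ENZY", 0)  # OTG 10
        p_hi = group_composition(spec, "ENZY", 7)  # OTG 22
        vmf_mask = np.array([a in set("EGKNQSADHIPRTV") for a in AA_ALPHABET])
        assert p_lo[vmf_mask].sum() - p_hi[vmf_mask].sum() == pytest.approx(
            0.2 * 12 / 100, abs=1e-12
        )
        assert np.allclose(p_lo.sum(), 1.0) and np.allclose(p_hi.sum(), 1.0)

    def test_impossible_gradient_rejected_at_validation(self):
        with pytest.raises(InputError):
            small_spec(gradients=(PlantedGradient("ENZY", "VMf", -10.0, "OTG"),))

    def test_iid_dipeptide_expectation_matches_analytic(self, rng):
        """Under i.i.d. residue draws E[Tn] = 100 * sum p_i p_j over negative pairs."""
        from coldcomp.composition_metrics import dipeptide_pct

        table = generate_tm_table(9)
        spec = small_spec(proteins_per_group=300, dirichlet_concentration=1e12, groups=("ENZY",))
        prots, _ = generate_proteome(spec, 0)
        p = group_composition(spec, "ENZY", 0)
        idx = {a: i for i, a in enumerate(AA_ALPHABET)}
        expect = 100 * sum(
            p[idx[d[0]]] * p[idx[d[1]]] for d in DIPEPTIDES if table.weight[d] < 0
        )
        vals = [dipeptide_pct(pr, table)[0] for pr in prots]
        assert np.mean(vals) == pytest.approx(expect, abs=0.3)


class TestGrowthCurves:
    def test_noise_free_rate_recovery_within_2pct(self):
        spec = small_spec(od_noise_sd=0.0)
        for i in (0, 4, 7):
            for c in generate_growth_curves(spec, i):
                r = planted_rate(spec, i, c.temperature)
                if r > 0.02 and c.replicate == 1:
                    fit = fit_growth_rate(c)
                    assert fit.gr == pytest.approx(r, rel=0.02)

    def test_grid_planted_otg_recovered_exactly(self):
        spec = small_spec(od_noise_sd=0.0)
        reps = {}
        for c in generate_growth_curves(spec, 1):  # planted OTG 15, on the grid
            reps.setdefault(c.temperature, []).append(fit_growth_rate(c).gr)
        otg, _ = determine_otg(reps)
        assert otg == 15.0

    def test_twin_peak_tie_averages_to_18_5(self):
        spec = small_spec(od_noise_sd=0.0)
        reps = {}
        for c in generate_growth_curves(spec, 4):  # planted OTG 18.5
            reps.setdefault(c.temperature, []).append(fit_growth_rate(c).gr)
        otg, disp = determine_otg(reps)
        assert otg == pytest.approx(18.5)
        assert disp == 19

    def test_rate_peaks_at_planted_otg(self):
        spec = small_spec()
        for i in (0, 2, 6):
            otg = spec.planted_otg[i]
            grid = np.linspace(otg - 5, otg + 5, 41)
            rates = [planted_rate(spec, i, T) for T in grid]
            assert grid[int(np.argmax(rates))] == pytest.approx(otg, abs=0.26)


class TestTmTableGenerator:
    def test_exact_category_counts(self):
        t = generate_tm_table(1, frac_negative=0.25, frac_low=0.25)
        cats = [t.category(d) for d in DIPEPTIDES]
        assert cats.count("negative") == 100
        assert cats.count("low") == 100
        assert cats.count("other") == 200

    def test_all_negative(self):
        t = generate_tm_table(1, frac_negative=1.0, frac_low=0.0)
        assert all(t.category(d) == "negative" for d in DIPEPTIDES)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(InputError):
            generate_tm_table(1, frac_negative=0.7, frac_low=0.5)

    def test_tallies_match_brute_force(self, rng):
        t = generate_tm_table(int(rng.integers(1e6)), frac_negative=0.3, frac_low=0.2)
        n_neg = sum(1 for d in DIPEPTIDES if t.weight[d] < 0)
        n_low = sum(1 for d in DIPEPTIDES if 0 <= t.weight[d] < t.low_threshold)
        assert n_neg == 120 and n_low == 80


class TestSpecValidation:
    def test_mismatched_planted_lists(self):
        with pytest.raises(InputError):
            SyntheticStudySpec(planted_otg=(10, 15), planted_gr=(1.0,) * 8)

    def test_unknown_gradient_metric(self):
        with pytest.raises(InputError):
            small_spec(gradients=(PlantedGradient("ENZY", "Tn", -0.1),))

    def test_gradient_group_must_exist(self):
        with pytest.raises(InputError):
            small_spec(gradients=(PlantedGradient("GLYC", "VMf", -0.1),))

    def test_default_recovery_spec_mirrors_study_design(self):
        spec = default_recovery_spec(seed=0)
        assert len(spec.organism_ids) == 8
        assert spec.otg_display == (10, 15, 15, 15, 19, 19, 22, 22)
        assert spec.temperatures == (4.0, 10.0, 15.0, 22.0, 30.0)
        assert spec.replicates == 3
        assert sum(g > 1.0 for g in spec.planted_gr) == 4
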