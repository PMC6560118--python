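"""Dose-factor matrix operations, intestine partition, organ doses,
tumor sphere model, and the RD% comparison statistic."""

import numpy as np
import pandas as pd
import pytest

import mousedosim as md
from mousedosim.dose import (
    DoseFactorMatrix,
    SphereDFTable,
    olinda2_sphere_table,
    toy_mouse_dfm,
)
from mousedosim.errors import ConfigurationError, DomainError, InvalidArgumentError


def random_dfm(rng, organs=("a", "b", "c")):
    n = len(organs)
    entries = pd.DataFrame(
        rng.uniform(0.5, 5.0, (n, n)) + np.diag(rng.uniform(50, 500, n)),
        index=organs,
        columns=organs,
    )
    masses = {o: rng.uniform(0.1, 2.0) for o in organs}
    return DoseFactorMatrix(entries=entries, reference_masses=masses)


class TestRescaleMasses:
    def test_reference_masses_leave_matrix_unchanged(self):
        dfm = toy_mouse_dfm()
        out = md.rescale_masses(dfm, dict(dfm.reference_masses))
        assert np.allclose(out.entries.values, dfm.entries.values)

    def test_electron_self_dose_inverse_mass(self):
        dfm = toy_mouse_dfm()
        ref = dfm.reference_masses["liver"]
        out = md.rescale_masses(dfm, {"liver": ref / 2.0})
        assert out.electron.at["liver", "liver"] == pytest.approx(
            2.0 * dfm.electron.at["liver", "liver"]
        )

    def test_photon_self_dose_two_thirds_power(self):
        dfm = toy_mouse_dfm()
        ref = dfm.reference_masses["kidneys"]
        out = md.rescale_masses(dfm, {"kidneys": ref / 2.0})
        assert out.photon.at["kidneys", "kidneys"] == pytest.approx(
            2.0 ** (2.0 / 3.0) * dfm.photon.at["kidneys", "kidneys"]
        )

    def test_cross_terms_unchanged(self):
        dfm = toy_mouse_dfm()
        out = md.rescale_masses(dfm, {"liver": 0.5})
        assert out.entries.at["liver", "heart"] == dfm.entries.at["liver", "heart"]
        assert out.entries.at["heart", "liver"] == dfm.entries.at["heart", "liver"]

    def test_unsplit_matrix_scales_whole_entry(self):
        rng = np.random.default_rng(1)
        dfm = random_dfm(rng)
        ref = dfm.reference_masses["a"]
        out = md.rescale_masses(dfm, {"a": ref / 3.0})
        assert out.entries.at["a", "a"] == pytest.approx(3.0 * dfm.entries.at["a", "a"])

    def test_unknown_organ_lists_valid_names(self):
        dfm = toy_mouse_dfm()
        with pytest.raises(ConfigurationError, match="liver"):
            md.rescale_masses(dfm, {"brain": 0.4})

    def test_rescale_commutes_with_dose_summation(self):
        """Rescaling then summing doses equals summing with an oracle that
        applies the scale factors term by term."""
        rng = np.random.default_rng(7)
        dfm = random_dfm(rng)
        actual = {o: m * rng.uniform(0.5, 1.5) for o, m in dfm.reference_masses.items()}
        tiacs = {o: rng.uniform(0.1, 5.0) for o in dfm.sources}
        report = md.organ_doses(tiacs, md.rescale_masses(dfm, actual))
        for target in dfm.targets:
            oracle = 0.0
            for source in dfm.sources:
                df = dfm.df(target, source)
                if source == target:
                    df *= dfm.reference_masses[source] / actual[source]
                oracle += tiacs[source] * df
            assert report.doses[target] == pytest.approx(oracle, rel=1e-12)


class TestPartitionIntestine:
    def test_worked_example(self):
        parts = md.partition_intestine(0.8, 4.0)
        assert parts["small_intestine"]["tiac"] == pytest.approx(0.6)
        assert parts["small_intestine"]["mass_g"] == pytest.approx(3.0)
        assert parts["large_intestine"]["tiac"] == pytest.approx(0.2)
        assert parts["large_intestine"]["mass_g"] == pytest.approx(1.0)

    def test_zero_tiac(self):
        parts = md.partition_intestine(0.0, 2.0)
        assert parts["small_intestine"]["tiac"] == 0.0
        assert parts["large_intestine"]["tiac"] == 0.0

    def test_exact_conservation_and_ratio(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tiac, mass = rng.uniform(0.01, 10.0, 2)
            parts = md.partition_intestine(tiac, mass)
            si, lli = parts["small_intestine"], parts["large_intestine"]
            assert si["tiac"] + lli["tiac"] == tiac  # exact, not approx
            assert si["mass_g"] + lli["mass_g"] == mass
            assert si["tiac"] / lli["tiac"] == pytest.approx(3.0)


class TestOrganDoses:
    def test_single_source_identity(self):
        entries = pd.DataFrame([[7.5]], index=["liver"], columns=["liver"])
        dfm = DoseFactorMatrix(entries=entries, reference_masses={"liver": 1.0})
        report = md.organ_doses({"liver": 1.0}, dfm)
        assert report.doses["liver"] == pytest.approx(7.5)

    def test_linearity_in_tiacs(self):
        rng = np.random.default_rng(2)
        dfm = random_dfm(rng, organs=("w", "x", "y", "z"))
        tiacs = {o: rng.uniform(0.1, 2.0) for o in dfm.sources}
        doubled = {o: 2 * v for o, v in tiacs.items()}
        r1 = md.organ_doses(tiacs, dfm)
        r2 = md.organ_doses(doubled, dfm)
        for t in dfm.targets:
            assert r2.doses[t] == pytest.approx(2 * r1.doses[t], rel=1e-12)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(9)
        dfm = random_dfm(rng, organs=("w", "x", "y", "z"))
        tiacs = {o: rng.uniform(0.1, 2.0) for o in dfm.sources}
        report = md.organ_doses(tiacs, dfm)
        for target in dfm.targets:
            oracle = sum(tiacs[s] * dfm.df(target, s) for s in dfm.sources)
            assert report.doses[target] == pytest.approx(oracle, rel=1e-12)

    def test_source_order_irrelevant(self):
        rng = np.random.default_rng(4)
        dfm = random_dfm(rng)
        tiacs = {o: rng.uniform(0.1, 2.0) for o in dfm.sources}
        reversed_tiacs = dict(reversed(list(tiacs.items())))
        r1, r2 = md.organ_doses(tiacs, dfm), md.organ_doses(reversed_tiacs, dfm)
        assert r1.doses == r2.doses

    def test_missing_source_rejected(self):
        dfm = toy_mouse_dfm()
        with pytest.raises(ConfigurationError):
            md.organ_doses({"spleen": 1.0}, dfm)

    def test_rest_of_body_falls_back_to_total_body(self):
        entries = pd.DataFrame(
            [[5.0, 1.0]], index=["liver"], columns=["liver", "total_body"]
        )
        dfm = DoseFactorMatrix(entries=entries, reference_masses={"liver": 1.0})
        report = md.organ_doses({"liver": 1.0, "rest_of_body": 2.0}, dfm)
        assert report.doses["liver"] == pytest.approx(7.0)
        assert any("total_body" in f for f in report.flags)


class TestTumorDose:
    def test_reference_table_at_one_gram(self):
        # TIAC of 1 h in a 1 g sphere -> 1.11E+02 mGy
        assert md.tumor_dose(1.0, 1.0, olinda2_sphere_table()) == pytest.approx(111.0)

    def test_zero_tiac(self):
        assert md.tumor_dose(0.0, 1.0, olinda2_sphere_table()) == 0.0

    def test_loglog_interpolation_sanity(self):
        """DF at 1 g interpolated from the 0.5 and 2 g neighbors lies within
        15% of the tabulated value."""
        table = olinda2_sphere_table()
        neighbors = SphereDFTable(
            masses_g=np.array([0.5, 2.0]), dfs=np.array([table(0.5), table(2.0)])
        )
        assert neighbors(1.0) == pytest.approx(table(1.0), rel=0.15)

    def test_mass_domain_enforced(self):
        with pytest.raises(DomainError):
            md.tumor_dose(1.0, 30.0, olinda2_sphere_table())

    def test_ellipsoid_model_as_sphere_source(self, tb):
        df = md.tumor_dose(
            1.0, 1.0, lambda m: md.dose_factor(tb, md.Ellipsoid.sphere(mass_g=m))
        )
        assert df == pytest.approx(114.0, rel=0.05)


class TestRelativeDifference:
    def test_liver_row(self):
        assert md.relative_difference(5.90e2, 5.24e2) == pytest.approx(12.60, abs=0.005)

    def test_kidneys_row(self):
        assert md.relative_difference(3.32e2, 3.89e2) == pytest.approx(-14.65, abs=0.005)

    def test_identity(self):
        assert md.relative_difference(3.0, 3.0) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(InvalidArgumentError):
            md.relative_difference(1.0, 0.0)


class TestDoseFactorMatrixValidation:
    def test_negative_df_rejected(self):
        entries = pd.DataFrame([[-1.0]], index=["a"], columns=["a"])
        with pytest.raises(InvalidArgumentError):
            DoseFactorMatrix(entries=entries, reference_masses={"a": 1.0})

    def test_component_sum_mismatch_rejected(self):
        entries = pd.DataFrame([[10.0]], index=["a"], columns=["a"])
        bad = pd.DataFrame([[3.0]], index=["a"], columns=["a"])
        with pytest.raises(InvalidArgumentError):
            DoseFactorMatrix(
                entries=entries,
                reference_masses={"a": 1.0},
                electron=bad,
                photon=bad,
            )

    def test_packaged_toy_matrix_consistent(self):
        dfm = toy_mouse_dfm()
        assert np.allclose(
            dfm.electron.values + dfm.photon.values, dfm.entries.values
        )
        for organ in dfm.sources:
            assert dfm.df(organ, organ) > 0
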