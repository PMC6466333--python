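"""Exposure dosimetry and risk indexing: published-table reproduction,
linearity, coefficient modes, grading matrix and the hazard projection."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

import fertrisk as fr
from fertrisk.metals import Metal

from conftest import region_params, survey_medians
from expected_tables import (
    CELL_RTOL,
    CR_PRINTED,
    HI_PRINTED,
    HQ_PRINTED,
    TCR_PRINTED,
)

PATHWAY_INDEX = {"oral": 0, "dermal": 1, "respiratory": 2, "total": 3}


@pytest.fixture(scope="module")
def reports(soil_limits):
    """Risk reports for all regions at background + one year of input."""
    out = {}
    for region in ("north", "northwest", "northeast", "northern"):
        out[region] = fr.assess(
            region_params(region), survey_medians(region), mode="as_published"
        )
    return out


class TestDoses:
    def test_oral_dose_north_arsenic(self, exposure):
        # Qi = background 8.65 + one year's flux
        qi = 8.65 + fr.annual_input(6.96, region_params("north"))
        assert fr.oral_dose(qi, exposure, Metal.As) == pytest.approx(3.66e-6, rel=5e-3)

    def test_zero_soil_concentration_zero_dose(self, exposure):
        for fn in (fr.oral_dose, fr.dermal_dose, fr.respiratory_dose):
            assert fn(0.0, exposure, Metal.Cr) == 0.0

    @given(qi=st.floats(0.01, 1e4), k=st.floats(0.1, 50.0))
    def test_every_dose_linear_in_soil_concentration(self, exposure, qi, k):
        for fn in (fr.oral_dose, fr.dermal_dose, fr.respiratory_dose):
            d1 = fn(qi, exposure, Metal.Cd)
            dk = fn(k * qi, exposure, Metal.Cd)
            assert dk == pytest.approx(k * d1, rel=1e-12)

    def test_mode_ratio_is_exactly_gamma_over_beta(self, exposure):
        for m in fr.METALS:
            pub = fr.dermal_dose(10.0, exposure, m, "as_published")
            wri = fr.dermal_dose(10.0, exposure, m, "as_written")
            assert wri / pub == pytest.approx(
                exposure.gamma[m] / exposure.beta[m], rel=1e-12
            )

    def test_mode_ratio_respiratory_theta_over_beta(self, exposure):
        for m in fr.METALS:
            pub = fr.respiratory_dose(10.0, exposure, m, "as_published")
            wri = fr.respiratory_dose(10.0, exposure, m, "as_written")
            assert wri / pub == pytest.approx(
                exposure.theta[m] / exposure.beta[m], rel=1e-12
            )

    def test_oral_identical_between_modes(self, exposure):
        assert fr.oral_dose(5.0, exposure, Metal.Pb, "as_written") == fr.oral_dose(
            5.0, exposure, Metal.Pb, "as_published"
        )

    def test_modes_agree_where_beta_equals_theta(self, exposure):
        # As has beta = theta = 1, so inhalation agrees across modes
        assert fr.respiratory_dose(8.74, exposure, Metal.As, "as_written") == (
            fr.respiratory_dose(8.74, exposure, Metal.As, "as_published")
        )


class TestPublishedRiskTables:
    @pytest.mark.parametrize("region", ["north", "northwest", "northeast"])
    def test_hazard_quotient_cells(self, reports, region):
        hq = reports[region].hq
        for metal, printed in HQ_PRINTED[region].items():
            for pathway, idx in PATHWAY_INDEX.items():
                assert hq.loc[metal, pathway] == pytest.approx(
                    printed[idx], rel=CELL_RTOL
                ), f"{region} {metal} {pathway}"

    @pytest.mark.parametrize("region", ["north", "northwest", "northeast"])
    def test_cancer_risk_cells(self, reports, region):
        cr = reports[region].cr
        for metal, printed in CR_PRINTED[region].items():
            for pathway, idx in PATHWAY_INDEX.items():
                assert cr.loc[metal, pathway] == pytest.approx(
                    printed[idx], rel=CELL_RTOL
                ), f"{region} {metal} {pathway}"

    @pytest.mark.parametrize(
        "region", ["north", "northwest", "northeast", "northern"]
    )
    def test_hazard_index_and_total_cancer_risk(self, reports, region):
        assert round(reports[region].hi, 2) == HI_PRINTED[region]
        assert reports[region].tcr == pytest.approx(TCR_PRINTED[region], rel=5e-3)

    def test_decomposition_sums_exactly(self, reports):
        rep = reports["north"]
        assert rep.hi == pytest.approx(rep.hq["total"].sum(), rel=1e-14)
        assert rep.tcr == pytest.approx(rep.cr["total"].sum(), rel=1e-14)
        for frame in (rep.hq, rep.cr):
            assert frame["total"].equals(
                frame[["oral", "dermal", "respiratory"]].sum(axis=1)
            )

    def test_carcinogen_rows_only(self, reports):
        assert list(reports["north"].cr.index) == ["Cr", "Ni", "As", "Cd"]


class TestGrade:
    @pytest.mark.parametrize(
        "hi, tcr, label",
        [
            (0.24, 6.29e-4, "High risk"),   # the pooled-region verdict
            (0.0, 0.0, "Low risk"),
            (0.6, 5e-5, "High risk"),
            (0.25, 1e-6, "Low risk"),       # right-closed band edges
            (0.26, 1e-6, "Low risk"),
            (0.26, 1.1e-6, "Moderate risk"),
            (0.9, 2e-4, "Extreme risk"),
            (0.1, 2e-5, "Moderate risk"),
        ],
    )
    def test_matrix_lookup(self, hi, tcr, label):
        assert fr.grade(hi, tcr).label == label

    def test_hi_above_one_clamps_with_flag(self):
        g = fr.grade(1.7, 1e-7)
        assert g.hi_band == 3 and g.hi_above_one
        assert g.label == "High risk"

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fr.grade(-0.1, 1e-6)

    def test_all_region_reports_grade_high(self, reports):
        # TCR above 1e-4 with HI below 0.25 grades high everywhere
        for region, rep in reports.items():
            assert rep.grade.label == "High risk"


class TestYearsToHazardThreshold:
    @staticmethod
    def stepping_oracle(params, qp, threshold=1.0):
        """Independent year-by-year walk to the threshold crossing."""
        ep = fr.load_exposure_parameters()
        tox = fr.load_toxicity_parameters()
        for n in range(100_000):
            qi = {m: params.Q0[m] + n * qp[m] for m in fr.METALS}
            _, hi = fr.hazard_quotients(fr.dose_profile(qi, ep), tox)
            if hi >= threshold:
                return n
        return math.inf

    @pytest.mark.parametrize("region", ["north", "northwest", "northeast"])
    def test_closed_form_matches_stepping_oracle(self, region):
        params = region_params(region)
        medians = survey_medians(region)
        qp = {m: fr.annual_input(medians[m], params) for m in fr.METALS}
        closed = fr.years_to_hi_threshold(params, qp, threshold=1.0)
        crossing = self.stepping_oracle(params, qp)
        assert crossing - 1 < closed <= crossing

    def test_threshold_already_met_is_zero_years(self):
        params = region_params("north")
        qp = {m: 0.01 for m in fr.METALS}
        hi0 = fr.years_to_hi_threshold(params, qp, threshold=1e-9)
        assert hi0 == 0.0

    def test_zero_input_never_crosses(self):
        params = region_params("north")
        assert fr.years_to_hi_threshold(
            params, {m: 0.0 for m in fr.METALS}, threshold=1.0
        ) == math.inf

    def test_doubling_slope_halves_remaining_years(self):
        params = region_params("north")
        medians = survey_medians("north")
        qp = {m: fr.annual_input(medians[m], params) for m in fr.METALS}
        qp2 = {m: 2 * v for m, v in qp.items()}
        y1 = fr.years_to_hi_threshold(params, qp)
        y2 = fr.years_to_hi_threshold(params, qp2)
        assert y2 == pytest.approx(y1 / 2, rel=1e-12)
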