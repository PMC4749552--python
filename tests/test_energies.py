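"""Energy-table post-processing: corrections, thresholds, activation score."""

import numpy as np
import pandas as pd
import pytest

from brafscan.codons import MutationKey
from brafscan.energies import (
    ACTIVE,
    INACTIVE,
    ConfigurationError,
    EnergyRecord,
    FormatError,
    MissingDataError,
    ThresholdConfig,
    UndefinedCorrelationError,
    activation_score,
    classify_destabilizing,
    correlate_with_phenotype,
    enumerate_mutation_space,
    loop_presence_correction,
    pairwise_state_correlation,
    parse_ddg_table,
    saltbridge_correction,
    state_average,
    summarize_energies,
    write_ddg_table,
)
from brafscan.ensemble import PresenceProfile

CFG = ThresholdConfig()

FIXTURE_TABLE = """\
template\tmutation\tddG_total\tddG_solvH\tloop
4EHE\tV600E\t2.50\t1.00\t3.10
4MNE\tV600V\t0.00\t0.00\t0.00
4EHE\tE600A\t0.04\t-0.10\t0.05
"""


def make_profile(fractions: dict[int, float], n: int = 28) -> PresenceProfile:
    table = pd.DataFrame(
        {
            "presence_fraction": pd.Series(fractions, dtype=float),
            "mean_normalized_bfactor": 0.0,
            "n_structures": n,
        }
    )
    table.index.name = "residue_number"
    return PresenceProfile(table=table, n_structures=n)


class TestParsing:
    def test_fixture_rows_become_typed_records(self):
        records = parse_ddg_table(FIXTURE_TABLE)
        assert len(records) == 3
        assert records[0].state == INACTIVE and records[1].state == ACTIVE
        assert records[1].mutation.is_self  # V600V control row
        assert records[2].ddg_total == pytest.approx(0.04)
        assert records[0].terms["loop"] == pytest.approx(3.10)

    def test_missing_energy_column_is_a_format_error(self):
        with pytest.raises(FormatError):
            parse_ddg_table("template\tmutation\n4EHE\tV600E\n")

    def test_unmapped_template_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            parse_ddg_table("template\tmutation\tddG_total\nXXXX\tV600E\t1.0\n")

    def test_write_parse_roundtrip(self):
        records = parse_ddg_table(FIXTURE_TABLE)
        again = parse_ddg_table(write_ddg_table(records))
        assert again == records


class TestEnumeration:
    def test_full_scan_is_1400_models(self):
        assert len(enumerate_mutation_space()) == 14 * 20 * 5

    def test_single_position_single_template(self):
        space = enumerate_mutation_space({600: "V"}, templates=("4EHE",))
        assert len(space) == 20
        assert sum(1 for _, m in space if m.is_self) == 1

    def test_no_templates_gives_empty_list(self):
        assert enumerate_mutation_space({600: "V"}, templates=()) == []


class TestThreshold:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.80, False), (0.81, True), (0.8 + 1e-9, True), (-1.0, False)],
    )
    def test_strictly_greater_than_0p8(self, value, expected):
        assert classify_destabilizing(value, CFG) is expected

    def test_non_finite_rejected(self):
        with pytest.raises(FormatError):
            classify_destabilizing(float("nan"), CFG)


class TestStateAverage:
    def test_mean_over_templates(self):
        key = MutationKey.parse("V600E")
        records = [
            EnergyRecord("4EHE", INACTIVE, key, 1.0, 0.0),
            EnergyRecord("3TV6", INACTIVE, key, 3.0, 0.0),
        ]
        assert state_average(records, key, INACTIVE) == pytest.approx(2.0)

    def test_single_template_passthrough(self):
        key = MutationKey.parse("V600E")
        records = [EnergyRecord("4MNE", ACTIVE, key, 0.7, 0.0)]
        assert state_average(records, key, ACTIVE) == pytest.approx(0.7)

    def test_missing_state_is_an_error(self):
        key = MutationKey.parse("V600E")
        records = [EnergyRecord("4MNE", ACTIVE, key, 0.7, 0.0)]
        with pytest.raises(MissingDataError):
            state_average(records, key, INACTIVE)

    def test_matches_independent_recomputation(self, energy_records):
        rng = np.random.default_rng(4)
        mutations = list({r.mutation for r in energy_records})
        for key in rng.choice(len(mutations), size=10, replace=False):
            mutation = mutations[int(key)]
            for state in (ACTIVE, INACTIVE):
                manual = np.mean(
                    [r.ddg_total for r in energy_records
                     if r.mutation == mutation and r.state == state]
                )
                assert state_average(energy_records, mutation, state) == pytest.approx(manual)


class TestPairwiseCorrelation:
    def test_unit_diagonal_and_symmetry(self, energy_records):
        corr = pairwise_state_correlation(energy_records)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_insufficient_overlap_rejected(self):
        key = MutationKey.parse("V600E")
        records = [EnergyRecord("4EHE", INACTIVE, key, 1.0, 0.0),
                   EnergyRecord("3TV6", INACTIVE, key, 1.1, 0.0)]
        with pytest.raises(MissingDataError):
            pairwise_state_correlation(records)


class TestLoopCorrection:
    def test_full_presence_leaves_energy_unchanged(self):
        profile = make_profile({600: 1.0})
        assert loop_presence_correction(2.0, 600, profile, CFG) == pytest.approx(2.0)

    def test_multiplicative_weighting_at_70_percent(self):
        profile = make_profile({600: 0.70})
        assert loop_presence_correction(2.0, 600, profile, CFG) == pytest.approx(1.4)

    def test_active_state_never_corrected(self):
        profile = make_profile({600: 0.1})
        assert loop_presence_correction(2.0, 600, profile, CFG, state=ACTIVE) == 2.0

    def test_non_loop_position_unchanged(self):
        profile = make_profile({487: 0.5})
        assert loop_presence_correction(2.0, 487, profile, CFG) == 2.0

    def test_loop_position_missing_from_profile_rejected(self):
        profile = make_profile({601: 0.5})
        with pytest.raises(ConfigurationError):
            loop_presence_correction(2.0, 600, profile, CFG)

    def test_never_amplifies(self, profile28):
        rng = np.random.default_rng(7)
        for _ in range(50):
            e = float(rng.normal(0, 3))
            pos = int(rng.integers(580, 616))
            corrected = loop_presence_correction(e, pos, profile28, CFG)
            assert abs(corrected) <= abs(e) + 1e-12


class TestSaltBridge:
    @pytest.mark.parametrize(
        "label,expected_is_credit",
        [
            ("T599E", True),   # phosphomimetic at Thr599
            ("T599D", True),
            ("K601E", True),   # engineered Glu reaching Arg575
            ("S602D", True),
            ("V600E", False),  # position 600 points away from Arg575
            ("V600D", False),
            ("T599A", False),  # not a phosphomimetic residue
            ("L597E", False),  # not a phospho-position
        ],
    )
    def test_credit_rules(self, label, expected_is_credit):
        value = saltbridge_correction(MutationKey.parse(label), CFG)
        assert value == (CFG.saltbridge_value if expected_is_credit else 0.0)

    def test_value_must_be_favourable(self):
        with pytest.raises(ConfigurationError):
            ThresholdConfig(saltbridge_value=1.0)


class TestActivationScore:
    def test_all_zero_inputs_score_zero(self):
        assert activation_score(0.0, 0.0, 0.0, 0.0) == 0.0

    def test_component_arithmetic(self):
        assert activation_score(2.0, 0.5, -0.3) == pytest.approx(1.2)

    def test_saltbridge_credit_raises_the_score(self):
        base = activation_score(2.0, 0.5, -0.3, saltbridge=0.0)
        credited = activation_score(2.0, 0.5, -0.3, saltbridge=-2.0)
        assert credited == pytest.approx(base + 2.0)

    def test_missing_component_is_an_error(self):
        with pytest.raises(MissingDataError):
            activation_score(float("nan"), 0.5, -0.3)


class TestPhenotypeCorrelation:
    def test_perfectly_linear(self):
        r, r2 = correlate_with_phenotype([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_anti_linear(self):
        r, _ = correlate_with_phenotype([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate_with_phenotype([1, 1, 1], [1, 2, 3])

    def test_rsq_tracks_configured_noise(self):
        # signal + noise with known variance ratio: R^2 ~ var_s/(var_s+var_n)
        rng = np.random.default_rng(12)
        signal = rng.normal(0, 2.0, 4000)
        noisy = signal + rng.normal(0, 1.0, 4000)
        _, r2 = correlate_with_phenotype(signal, noisy)
        assert r2 == pytest.approx(4 / 5, abs=0.04)


class TestSummaries:
    def test_self_substitutions_never_destabilizing_and_score_near_zero(
        self, energy_records, profile28
    ):
        summaries = summarize_energies(energy_records, profile28)
        selfs = [s for s in summaries if s.mutation.is_self]
        assert len(selfs) == 14
        for s in selfs:
            assert not s.destabilizing_inactive
            assert not s.destabilizing_active
            assert abs(s.activation_score) < 1.0

    def test_activating_loop_mutation_outranks_neutral_one(
        self, energy_records, profile28
    ):
        summaries = {str(s.mutation): s for s in summarize_energies(energy_records, profile28)}
        assert (
            summaries["V600E"].activation_score
            > summaries["V600V"].activation_score
        )

    def test_destabilizing_flags_follow_the_threshold(self, energy_records, profile28):
        for s in summarize_energies(energy_records, profile28):
            assert s.destabilizing_inactive == (s.mean_ddg_inactive > 0.8)
            assert s.destabilizing_active == (s.mean_ddg_active > 0.8)

    def test_loop_correction_only_within_loop_region(self, energy_records, profile28):
        for s in summarize_energies(energy_records, profile28):
            if CFG.in_loop(s.mutation.position):
                expected = s.loop_energy * profile28.presence(s.mutation.position)
                assert s.loop_energy_corrected == pytest.approx(expected)
            else:
                assert s.loop_energy_corrected == s.loop_energy
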