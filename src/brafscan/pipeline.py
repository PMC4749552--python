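"""End-to-end orchestration: simulate → profile → summaries → features → forests."""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .codons import Codon, accessibility_table, load_reference_codons
from .ensemble import PresenceProfile, profile_from_pdb_strings
from .energies import EnergySummary, ThresholdConfig, summarize_energies
from .features import FrequencyRecord, build_feature_matrix
from .forest import ForestConfig, ProtocolResult, run_protocol
from .simulate import (
    SyntheticConfig,
    generate_energy_tables,
    generate_frequencies,
    generate_structure_ensemble,
)


@dataclass(frozen=True)
class Cohort:
    """A synthetic study cohort: inputs plus the assembled feature matrix."""

    profile: PresenceProfile
    summaries: tuple[EnergySummary, ...]
    frequencies: tuple[FrequencyRecord, ...]
    X: pd.DataFrame
    y: pd.Series
    counts: pd.Series


@dataclass(frozen=True)
class PipelineResult:
    cohort: Cohort
    protocol: ProtocolResult

    # convenience pass-throughs
    @property
    def profile(self) -> PresenceProfile:
        return self.cohort.profile

    @property
    def summaries(self) -> tuple[EnergySummary, ...]:
        return self.cohort.summaries

    @property
    def frequencies(self) -> tuple[FrequencyRecord, ...]:
        return self.cohort.frequencies

    @property
    def X(self) -> pd.DataFrame:
        return self.cohort.X

    @property
    def y(self) -> pd.Series:
        return self.cohort.y

    @property
    def counts(self) -> pd.Series:
        return self.cohort.counts


def generate_cohort(
    seed: int,
    sim_cfg: SyntheticConfig | None = None,
    threshold_cfg: ThresholdConfig | None = None,
    n_structures: int = 28,
) -> Cohort:
    """Generate all synthetic inputs and assemble the feature matrix.

    ``seed`` overrides the simulation config's seed so one integer fixes the
    whole cohort.
    """
    sim_cfg = replace(sim_cfg or SyntheticConfig(), seed=seed)
    threshold_cfg = threshold_cfg or ThresholdConfig()

    records = generate_energy_tables(sim_cfg)
    ensemble = generate_structure_ensemble(sim_cfg, n_structures=n_structures)
    profile = profile_from_pdb_strings(ensemble, residue_range=sim_cfg.residue_range)
    summaries = summarize_energies(records, profile, threshold_cfg)

    reference = {
        pos: codon
        for pos, codon in load_reference_codons().items()
        if pos in sim_cfg.positions
    }
    missing = set(sim_cfg.positions) - set(reference)
    if missing:
        raise ValueError(f"no bundled reference codon for position(s) {sorted(missing)}")
    accessibility = accessibility_table(reference)

    # assemble once against placeholder counts to obtain the raw feature
    # matrix the count model needs, then reassemble with the drawn response
    keys = [s.mutation for s in summaries]
    placeholder = [FrequencyRecord(mutation=k, count=0, response=0.0) for k in keys]
    X_raw, _, _ = build_feature_matrix(summaries, accessibility, placeholder)
    frequencies = generate_frequencies(X_raw, sim_cfg)
    X, y, counts = build_feature_matrix(summaries, accessibility, frequencies)
    return Cohort(
        profile=profile,
        summaries=tuple(summaries),
        frequencies=tuple(frequencies),
        X=X,
        y=y,
        counts=counts,
    )


def run_pipeline(
    seed: int,
    sim_cfg: SyntheticConfig | None = None,
    threshold_cfg: ThresholdConfig | None = None,
    forest_cfg: ForestConfig | None = None,
    n_structures: int = 28,
) -> PipelineResult:
    """Generate a synthetic cohort and run the full analysis on it.

    The master ``seed`` fixes the cohort and seeds the forest protocol, so the
    whole result is bit-reproducible from one integer.
    """
    cohort = generate_cohort(seed, sim_cfg, threshold_cfg, n_structures)
    protocol = run_protocol(cohort.X, cohort.y, cohort.counts, master_seed=seed, cfg=forest_cfg)
    return PipelineResult(cohort=cohort, protocol=protocol)


def default_reference_codons() -> dict[int, Codon]:
    return load_reference_codons()
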