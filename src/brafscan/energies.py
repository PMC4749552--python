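"""Post-processing of per-mutation folding-energy (ΔΔG) tables.

The inputs are mutational-scan tables in the style of empirical force-field
output: one row per mutation per template structure, carrying the total
folding free-energy change ΔΔG (kcal/mol, positive = destabilising) plus a
term decomposition (hydrophobic solvation, and optionally an activation-loop
restricted energy). Template structures are classified as active-like or
inactive-like conformations of the kinase domain.

Corrections applied on top of the raw energies:

* state averaging across the templates of each conformation;
* strict destabilisation threshold (> 0.8 kcal/mol, two SD of the force
  field's error);
* loop-presence weighting — activation-segment loop energies from the
  inactive conformation are scaled by the fraction of ensemble structures
  resolving that residue, since mutations in flexible, rarely ordered regions
  unfold the domain less than the rigid-lattice energy suggests;
* phosphomimetic salt-bridge credit — Asp/Glu at the phospho-acceptor
  positions (Thr599, Ser602) and at Lys601 can reach Arg575 and stabilise the
  active conformation, so a favourable energy is added to the active-state
  term; position 600 points away from Arg575 and is excluded.

The composite activation score per mutation is

    score = corrected inactive-loop energy − (active ΔΔG + salt-bridge credit)
            + hydrophobic-solvation change (inactive)

high when the mutation releases the activation segment without wrecking the
active conformation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codons import AMINO_ACIDS, MutationKey
from .ensemble import PresenceProfile

ACTIVE = "active"
INACTIVE = "inactive"

DEFAULT_POCKET_RESIDUES: dict[int, str] = {
    468: "F", 485: "L", 487: "V", 497: "A", 498: "F", 525: "L",
    597: "L", 598: "A", 599: "T", 600: "V", 601: "K", 602: "S",
    603: "R", 604: "W",
}

DEFAULT_TEMPLATE_STATES: dict[str, str] = {
    "4MNE": ACTIVE, "3OG7": ACTIVE, "4MNF": ACTIVE,
    "4EHE": INACTIVE, "3TV6": INACTIVE,
}


class FormatError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


class MissingDataError(ValueError):
    pass


class UndefinedCorrelationError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds and corrections; defaults follow the BRAF analysis."""

    destabilization_threshold: float = 0.8  # kcal/mol, strict >
    loop_region: tuple[int, int] = (597, 615)  # Leu597–Gly615 activation-segment loop
    saltbridge_value: float = -2.0  # kcal/mol; placeholder magnitude, must be <= 0
    saltbridge_positions: frozenset[int] = frozenset({599, 601, 602})
    saltbridge_residues: frozenset[str] = frozenset({"D", "E"})

    def __post_init__(self) -> None:
        if self.destabilization_threshold <= 0:
            raise ConfigurationError("destabilization threshold must be positive")
        if self.saltbridge_value > 0:
            raise ConfigurationError("salt-bridge correction must be favourable (<= 0)")

    def in_loop(self, position: int) -> bool:
        lo, hi = self.loop_region
        return lo <= position <= hi


@dataclass(frozen=True)
class EnergyRecord:
    """ΔΔG of one mutation modelled on one template structure."""

    template_id: str
    state: str
    mutation: MutationKey
    ddg_total: float
    ddg_solv_h: float
    terms: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in (ACTIVE, INACTIVE):
            raise ConfigurationError(f"unknown state {self.state!r}")
        if not np.isfinite(self.ddg_total):
            raise FormatError(f"non-finite ddG for {self.mutation} on {self.template_id}")


@dataclass(frozen=True)
class EnergySummary:
    """Per-mutation state-averaged energies, corrections, and activation score."""

    mutation: MutationKey
    mean_ddg_inactive: float
    mean_ddg_active: float
    loop_energy: float
    loop_energy_corrected: float
    saltbridge_correction: float
    ddg_solv_h_inactive: float
    activation_score: float
    destabilizing_inactive: bool
    destabilizing_active: bool


_REQUIRED_COLUMNS = ("template", "mutation", "ddG_total")


def parse_ddg_table(
    table: str | io.TextIOBase,
    template_states: Mapping[str, str] | None = None,
) -> list[EnergyRecord]:
    """Parse a tab-delimited mutational-scan table into typed records.

    Required columns: ``template``, ``mutation`` (e.g. V600E), ``ddG_total``.
    ``ddG_solvH`` is used as the hydrophobic-solvation term when present
    (default 0). Any further numeric column is kept in the term decomposition.
    """
    template_states = template_states or DEFAULT_TEMPLATE_STATES
    buf = io.StringIO(table) if isinstance(table, str) else table
    df = pd.read_csv(buf, sep="\t", comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"energy table lacks required column(s): {missing}")
    unknown = set(df["template"]) - set(template_states)
    if unknown:
        raise ConfigurationError(f"templates without a state mapping: {sorted(unknown)}")
    term_cols = [c for c in df.columns if c not in (*_REQUIRED_COLUMNS, "ddG_solvH")]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            EnergyRecord(
                template_id=str(d["template"]),
                state=template_states[d["template"]],
                mutation=MutationKey.parse(str(d["mutation"])),
                ddg_total=float(d["ddG_total"]),
                ddg_solv_h=float(d.get("ddG_solvH", 0.0)),
                terms={c: float(d[c]) for c in term_cols if pd.notna(d[c])},
            )
        )
    return records


def write_ddg_table(records: Sequence[EnergyRecord]) -> str:
    """Serialise records to the tab-delimited format ``parse_ddg_table`` reads."""
    term_names = sorted({name for r in records for name in r.terms})
    rows = []
    for r in records:
        row = {
            "template": r.template_id,
            "mutation": str(r.mutation),
            "ddG_total": r.ddg_total,
            "ddG_solvH": r.ddg_solv_h,
        }
        row.update({name: r.terms.get(name, np.nan) for name in term_names})
        rows.append(row)
    return pd.DataFrame(rows).to_csv(sep="\t", index=False, float_format="%.6g")


def enumerate_mutation_space(
    reference: Mapping[int, str] | None = None,
    templates: Iterable[str] = tuple(DEFAULT_TEMPLATE_STATES),
) -> list[tuple[str, MutationKey]]:
    """Every (template, substitution) pair, including self-substitutions.

    With the default 14 pocket positions and 5 templates this is the full
    14 × 20 × 5 = 1400-model scan.
    """
    reference = reference or DEFAULT_POCKET_RESIDUES
    if not reference:
        raise ConfigurationError("need at least one position")
    out = []
    for template in templates:
        for position in sorted(reference):
            wt = reference[position]
            for target in AMINO_ACIDS:
                out.append((template, MutationKey(position=position, wt_aa=wt, mut_aa=target)))
    return out


def classify_destabilizing(mean_ddg: float, cfg: ThresholdConfig | None = None) -> bool:
    """True iff the state-averaged ΔΔG strictly exceeds the threshold (> 0.8 kcal/mol)."""
    cfg = cfg or ThresholdConfig()
    if not np.isfinite(mean_ddg):
        raise FormatError("mean ddG must be finite")
    return mean_ddg > cfg.destabilization_threshold


def state_average(records: Sequence[EnergyRecord], mutation: MutationKey, state: str) -> float:
    values = [r.ddg_total for r in records if r.mutation == mutation and r.state == state]
    if not values:
        raise MissingDataError(f"no {state} records for {mutation}")
    return float(np.mean(values))


def pairwise_state_correlation(records: Sequence[EnergyRecord]) -> pd.DataFrame:
    """Pearson correlation between templates over their shared mutations.

    Within-conformation template pairs are expected to correlate strongly;
    active-vs-inactive pairs poorly — the pattern that justifies treating the
    two conformations as distinct energy landscapes.
    """
    df = pd.DataFrame(
        {
            "template": [r.template_id for r in records],
            "mutation": [str(r.mutation) for r in records],
            "ddg": [r.ddg_total for r in records],
        }
    )
    wide = df.pivot_table(index="mutation", columns="template", values="ddg")
    if wide.shape[1] < 2:
        raise MissingDataError("need >= 2 templates for pairwise correlation")
    if wide.dropna().shape[0] < 3:
        raise MissingDataError("need >= 3 shared mutations for pairwise correlation")
    return wide.corr(method="pearson")


def loop_presence_correction(
    loop_energy: float,
    position: int,
    profile: PresenceProfile,
    cfg: ThresholdConfig | None = None,
    state: str = INACTIVE,
) -> float:
    """Scale an inactive-state loop energy by the residue's presence fraction.

    Only inactive-conformation energies at activation-loop positions are
    corrected; active-conformation energies pass through unchanged (the
    active templates resolve the segment only to position 600 and show no
    destabilisation needing correction).
    """
    cfg = cfg or ThresholdConfig()
    if state != INACTIVE or not cfg.in_loop(position):
        return loop_energy
    if position not in profile.table.index:
        raise ConfigurationError(f"loop position {position} missing from presence profile")
    return loop_energy * profile.presence(position)


def saltbridge_correction(mutation: MutationKey, cfg: ThresholdConfig | None = None) -> float:
    """Favourable energy for phosphomimetic Asp/Glu at Arg575-reachable positions.

    Zero at position 600, which points away from Arg575 in the active
    conformation regardless of the substitution.
    """
    cfg = cfg or ThresholdConfig()
    if mutation.position == 600:
        return 0.0
    if mutation.position in cfg.saltbridge_positions and mutation.mut_aa in cfg.saltbridge_residues:
        return cfg.saltbridge_value
    return 0.0


def activation_score(
    loop_energy_corrected: float,
    mean_ddg_active: float,
    ddg_solv_h_inactive: float,
    saltbridge: float = 0.0,
) -> float:
    """Composite score: corrected loop energy − corrected active ΔΔG + solvation term.

    The salt-bridge credit (≤ 0) is applied to the active-state term, so a
    phosphomimetic that stabilises the active conformation raises the score.
    """
    components = (loop_energy_corrected, mean_ddg_active, ddg_solv_h_inactive, saltbridge)
    if not all(np.isfinite(c) for c in components):
        raise MissingDataError(f"activation score needs finite components, got {components}")
    return loop_energy_corrected - (mean_ddg_active + saltbridge) + ddg_solv_h_inactive


def correlate_with_phenotype(
    scores: Sequence[float], phenotype: Sequence[float]
) -> tuple[float, float]:
    """Pearson r and R² between per-mutation scores and a measured phenotype."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise MissingDataError("need >= 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    r = float(stats.pearsonr(x, y).statistic)
    return r, r * r


def _loop_energy(inactive_records: Sequence[EnergyRecord], cfg: ThresholdConfig) -> float:
    """Inactive-loop energy: mean of the per-record ``loop`` term when present,
    else the total ΔΔG (loop-position mutations put their energy there anyway)."""
    with_term = [r.terms["loop"] for r in inactive_records if "loop" in r.terms]
    if with_term:
        return float(np.mean(with_term))
    return float(np.mean([r.ddg_total for r in inactive_records]))


def summarize_energies(
    records: Sequence[EnergyRecord],
    profile: PresenceProfile,
    cfg: ThresholdConfig | None = None,
) -> list[EnergySummary]:
    """Collapse per-template records into per-mutation corrected summaries."""
    cfg = cfg or ThresholdConfig()
    by_mutation: dict[MutationKey, list[EnergyRecord]] = {}
    for r in records:
        by_mutation.setdefault(r.mutation, []).append(r)

    summaries = []
    for mutation in sorted(by_mutation, key=lambda m: (m.position, m.mut_aa)):
        recs = by_mutation[mutation]
        inactive = [r for r in recs if r.state == INACTIVE]
        mean_inactive = state_average(recs, mutation, INACTIVE)
        mean_active = state_average(recs, mutation, ACTIVE)
        loop_energy = _loop_energy(inactive, cfg)
        loop_corrected = loop_presence_correction(
            loop_energy, mutation.position, profile, cfg, state=INACTIVE
        )
        salt = saltbridge_correction(mutation, cfg)
        solv_h = float(np.mean([r.ddg_solv_h for r in inactive]))
        summaries.append(
            EnergySummary(
                mutation=mutation,
                mean_ddg_inactive=mean_inactive,
                mean_ddg_active=mean_active,
                loop_energy=loop_energy,
                loop_energy_corrected=loop_corrected,
                saltbridge_correction=salt,
                ddg_solv_h_inactive=solv_h,
                activation_score=activation_score(loop_corrected, mean_active, solv_h, salt),
                destabilizing_inactive=classify_destabilizing(mean_inactive, cfg),
                destabilizing_active=classify_destabilizing(mean_active, cfg),
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[EnergySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "mutation": str(s.mutation),
                "mean_ddG_inactive": s.mean_ddg_inactive,
                "mean_ddG_active": s.mean_ddg_active,
                "loop_energy": s.loop_energy,
                "loop_energy_corrected": s.loop_energy_corrected,
                "saltbridge_correction": s.saltbridge_correction,
                "ddG_solvH_inactive": s.ddg_solv_h_inactive,
                "activation_score": s.activation_score,
                "destabilizing_inactive": s.destabilizing_inactive,
                "destabilizing_active": s.destabilizing_active,
            }
        )
    return pd.DataFrame(rows).set_index("mutation")
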