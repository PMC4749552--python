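"""Assembly of the seven-predictor feature matrix and the frequency response.

Predictors, one row per substitution:

1. ``inactive_destabilization`` — state-averaged ΔΔG of the inactive
   conformation (folding/misfolding propensity of the autoinhibited state);
2. ``active_destabilization`` — state-averaged ΔΔG of the active conformation;
3. ``loop_destabilization`` — presence-corrected inactive activation-loop
   energy (the segment-release driver);
4. ``nt_substitutions`` — minimum number of base changes required;
5. ``codon_usage_delta`` — change in codon-usage fraction;
6. ``salt_bridge`` — phosphomimetic salt-bridge credit (≤ 0);
7. ``hydrophobic_solvation`` — hydrophobic-solvation energy change.

The response is a monotone transform of the per-substitution cancer
occurrence count (log10(count+1) by default; raw counts span four orders of
magnitude, which would let the single top hotspot dominate any squared-error
fit).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .codons import AccessibilityRecord, MutationKey
from .energies import EnergySummary

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "inactive_destabilization",
    "active_destabilization",
    "loop_destabilization",
    "nt_substitutions",
    "codon_usage_delta",
    "salt_bridge",
    "hydrophobic_solvation",
)


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class FrequencyRecord:
    """Observed occurrence count of one substitution in tumours, plus its transform."""

    mutation: MutationKey
    count: int
    response: float


def transform_frequency(count: int, mode: str = "log10p1") -> float:
    """Monotone transform of an occurrence count (log10p1 | raw | binary)."""
    if count < 0:
        raise InputError(f"counts must be non-negative, got {count}")
    if mode == "log10p1":
        return math.log10(count + 1)
    if mode == "raw":
        return float(count)
    if mode == "binary":
        return float(count > 0)
    raise InputError(f"unknown transform mode {mode!r}")


def frequency_records(
    mutations: Sequence[MutationKey], counts: Sequence[int], mode: str = "log10p1"
) -> list[FrequencyRecord]:
    return [
        FrequencyRecord(mutation=m, count=int(c), response=transform_frequency(int(c), mode))
        for m, c in zip(mutations, counts)
    ]


def parse_frequency_table(text: str, mode: str = "log10p1") -> list[FrequencyRecord]:
    """Read a tab-delimited frequency file (columns: position, wt, mut, count)."""
    import io

    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#")
    required = {"position", "wt", "mut", "count"}
    if not required.issubset(df.columns):
        raise InputError(f"frequency table needs columns {sorted(required)}")
    keys = [
        MutationKey(position=int(p), wt_aa=str(w), mut_aa=str(m))
        for p, w, m in zip(df["position"], df["wt"], df["mut"])
    ]
    return frequency_records(keys, df["count"].tolist(), mode)


def write_frequency_table(records: Sequence[FrequencyRecord]) -> str:
    rows = [
        {"position": r.mutation.position, "wt": r.mutation.wt_aa, "mut": r.mutation.mut_aa,
         "count": r.count}
        for r in records
    ]
    return pd.DataFrame(rows).to_csv(sep="\t", index=False)


def build_feature_matrix(
    summaries: Sequence[EnergySummary],
    accessibility: Sequence[AccessibilityRecord],
    frequencies: Sequence[FrequencyRecord],
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Inner-join the three inputs into (X, response, raw counts).

    Rows are ordered by (position, mutant residue); mutations absent from any
    input are dropped with a warning. Returns the 7-column feature matrix,
    the transformed response, and the raw counts (kept for stratification).
    """
    summary_map = {s.mutation: s for s in summaries}
    access_map = {a.mutation: a for a in accessibility}
    freq_map = {f.mutation: f for f in frequencies}

    shared = set(summary_map) & set(access_map) & set(freq_map)
    union = set(summary_map) | set(access_map) | set(freq_map)
    dropped = union - shared
    if dropped:
        logger.warning(
            "dropping %d mutation(s) not covered by all inputs (e.g. %s)",
            len(dropped),
            sorted(str(m) for m in dropped)[:5],
        )
    if not shared:
        raise InputError("no mutation is covered by all three inputs")

    ordered = sorted(shared, key=lambda m: (m.position, m.mut_aa))
    index = pd.Index([str(m) for m in ordered], name="mutation")
    rows = []
    for m in ordered:
        s, a = summary_map[m], access_map[m]
        rows.append(
            (
                s.mean_ddg_inactive,
                s.mean_ddg_active,
                s.loop_energy_corrected,
                float(a.min_substitutions),
                a.usage_delta,
                s.saltbridge_correction,
                s.ddg_solv_h_inactive,
            )
        )
    X = pd.DataFrame(rows, index=index, columns=list(FEATURE_NAMES))
    if X.isna().any().any():
        raise InputError("assembled feature matrix contains missing values")
    y = pd.Series([freq_map[m].response for m in ordered], index=index, name="response")
    counts = pd.Series(
        [freq_map[m].count for m in ordered], index=index, name="count", dtype=int
    )
    return X, y, counts


def mutation_index(X: pd.DataFrame) -> list[MutationKey]:
    return [MutationKey.parse(label) for label in X.index]


def find_row(X: pd.DataFrame, mutation: MutationKey) -> int | None:
    """Positional row index of a mutation in the matrix, or None."""
    label = str(mutation)
    if label in X.index:
        return int(np.flatnonzero(X.index == label)[0])
    return None
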