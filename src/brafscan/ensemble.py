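"""Per-residue flexibility profiles from a crystal-structure ensemble.

Flexible regions of a kinase domain — above all the activation segment — are
often missing from electron density. Across an ensemble of structures of the
same domain, the fraction of structures in which a residue is resolved
("presence fraction") and the average of per-structure z-normalised B-factors
are complementary flexibility proxies: rarely resolved residues tend to carry
high B-factors where they are resolved at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class EnsembleInputError(ValueError):
    pass


@dataclass(frozen=True)
class ResidueObservation:
    """One residue in one structure: resolved (has a CA record) or not."""

    structure_id: str
    chain: str
    residue_number: int
    amino_acid: str
    resolved: bool
    bfactor: float | None

    def __post_init__(self) -> None:
        if self.resolved != (self.bfactor is not None):
            raise EnsembleInputError("bfactor must be present iff the residue is resolved")


@dataclass(frozen=True)
class PresenceProfile:
    """Per-residue presence fraction and mean normalised B-factor over an ensemble.

    ``table`` is indexed by residue number with columns ``presence_fraction``
    (0–1 scale) and ``mean_normalized_bfactor`` (NaN where never resolved).
    """

    table: pd.DataFrame
    n_structures: int

    def presence(self, position: int) -> float:
        if position not in self.table.index:
            raise EnsembleInputError(f"position {position} not covered by the profile")
        return float(self.table.loc[position, "presence_fraction"])


def parse_structure_residues(
    pdb_content: str,
    chain: str | None = None,
    residue_range: tuple[int, int] = (580, 620),
    structure_id: str | None = None,
) -> list[ResidueObservation]:
    """Extract one observation per residue number in ``residue_range``.

    A residue counts as resolved iff it has an alpha-carbon coordinate record;
    its B-factor is the CA temperature factor. When ``chain`` is None the
    first chain containing any residue in the range is used.
    """
    try:
        structure = gemmi.read_pdb_string(pdb_content)
    except (RuntimeError, ValueError) as exc:
        raise EnsembleInputError(f"malformed PDB content: {exc}") from exc
    if len(structure) == 0:
        raise EnsembleInputError("PDB content contains no model")
    model = structure[0]
    sid = structure_id or structure.name or "unnamed"
    lo, hi = residue_range

    def residues_in_range(ch: gemmi.Chain) -> dict[int, gemmi.Residue]:
        return {r.seqid.num: r for r in ch if lo <= r.seqid.num <= hi}

    if chain is not None:
        try:
            target = model[chain]
        except (KeyError, IndexError, ValueError):
            raise EnsembleInputError(f"chain {chain!r} not found in structure {sid}") from None
        found = residues_in_range(target)
        chain_name = chain
    else:
        chain_name, found = None, {}
        for ch in model:
            hit = residues_in_range(ch)
            if hit:
                chain_name, found = ch.name, hit
                break
        if chain_name is None:
            raise EnsembleInputError(
                f"no chain of structure {sid} covers residues {lo}-{hi}"
            )

    observations = []
    for num in range(lo, hi + 1):
        res = found.get(num)
        ca = res.find_atom("CA", "*") if res is not None else None
        resolved = ca is not None
        observations.append(
            ResidueObservation(
                structure_id=sid,
                chain=chain_name,
                residue_number=num,
                amino_acid=gemmi.find_tabulated_residue(res.name).one_letter_code.upper()
                if res is not None
                else "-",
                resolved=resolved,
                bfactor=float(ca.b_iso) if resolved else None,
            )
        )
    return observations


def _by_structure(
    observations: Sequence[ResidueObservation],
) -> dict[str, list[ResidueObservation]]:
    grouped: dict[str, list[ResidueObservation]] = {}
    for obs in observations:
        grouped.setdefault(obs.structure_id, []).append(obs)
    return grouped


def normalized_bfactors(observations: Sequence[ResidueObservation]) -> pd.Series:
    """Z-normalise resolved B-factors within one structure (mean 0, SD 1).

    A structure with zero B-factor variance contributes 0 for every resolved
    residue (with a warning), so flat-B structures do not distort averages.
    """
    resolved = [o for o in observations if o.resolved]
    if len(resolved) < 2:
        raise EnsembleInputError("normalisation needs >= 2 resolved residues per structure")
    values = np.array([o.bfactor for o in resolved], dtype=float)
    sd = values.std(ddof=0)
    if sd == 0:
        logger.warning(
            "structure %s has zero B-factor variance; contributing zeros",
            resolved[0].structure_id,
        )
        z = np.zeros_like(values)
    else:
        z = (values - values.mean()) / sd
    return pd.Series(z, index=[o.residue_number for o in resolved])


def presence_profile(observations: Sequence[ResidueObservation]) -> PresenceProfile:
    """Aggregate observations from many structures into a PresenceProfile.

    Presence fraction = resolved structures / total structures per residue
    (0–1 scale; multiply by 100 for reporting). Mean normalised B-factor
    averages the per-structure z-scores over the structures resolving the
    residue; NaN where never resolved.
    """
    grouped = _by_structure(observations)
    if not grouped:
        raise EnsembleInputError("no observations: need at least one structure")
    n = len(grouped)

    residues = sorted({o.residue_number for o in observations})
    resolved_counts = pd.Series(0, index=residues, dtype=float)
    z_sums = pd.Series(0.0, index=residues)
    z_counts = pd.Series(0, index=residues, dtype=float)
    for obs_list in grouped.values():
        n_resolved = 0
        for o in obs_list:
            if o.resolved:
                resolved_counts[o.residue_number] += 1
                n_resolved += 1
        if n_resolved < 2:
            # presence still counts; too little spread to normalise B-factors
            continue
        z = normalized_bfactors(obs_list)
        z_sums[z.index] += z.values
        z_counts[z.index] += 1

    with np.errstate(invalid="ignore"):
        mean_z = z_sums / z_counts.replace(0, np.nan)
    table = pd.DataFrame(
        {
            "presence_fraction": resolved_counts / n,
            "mean_normalized_bfactor": mean_z,
            "n_structures": n,
        },
        index=pd.Index(residues, name="residue_number"),
    )
    return PresenceProfile(table=table, n_structures=n)


def profile_from_pdb_strings(
    pdb_contents: Mapping[str, str] | Sequence[str],
    chain: str | None = None,
    residue_range: tuple[int, int] = (580, 620),
) -> PresenceProfile:
    """Convenience: parse many PDB texts and build their PresenceProfile."""
    if isinstance(pdb_contents, Mapping):
        items = list(pdb_contents.items())
    else:
        items = [(f"structure_{i:04d}", text) for i, text in enumerate(pdb_contents)]
    observations: list[ResidueObservation] = []
    for sid, text in items:
        observations.extend(
            parse_structure_residues(text, chain=chain, residue_range=residue_range, structure_id=sid)
        )
    return presence_profile(observations)
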