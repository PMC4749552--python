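"""Codon-level mutational accessibility.

Missense mutations differ in how many nucleotide substitutions they require:
changing Val600 (GTG) to Glu needs a single base change, while Lys or Asp
need two and His needs three. Because tumours acquire point mutations one
base at a time, the minimum substitution count is a strong determinant of
how often an otherwise-equivalent activating mutation is observed in cancer.
This module computes that count, the set of minimally distant mutant codons,
and the change in codon-usage fraction the substitution entails (a proxy for
translation-efficiency effects of moving to a rarer codon).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

from Bio.Data import CodonTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_CODON_RE = re.compile(r"^[ACGT]{3}$")


class InvalidInputError(ValueError):
    """Raised for malformed codons or non-encodable target residues."""


class ConfigurationError(ValueError):
    """Raised when required reference data (usage entries, codons) is absent."""


@dataclass(frozen=True)
class Codon:
    """A DNA codon: exactly three bases over {A,C,G,T}, stored uppercase."""

    bases: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "bases", self.bases.upper())
        if not _CODON_RE.match(self.bases):
            raise InvalidInputError(f"not a valid codon: {self.bases!r}")

    def hamming(self, other: "Codon") -> int:
        return sum(a != b for a, b in zip(self.bases, other.bases))

    def __str__(self) -> str:
        return self.bases


def _standard_code() -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@dataclass(frozen=True)
class GeneticCode:
    """A 64-entry codon → amino-acid map (stop = '*'); standard table by default."""

    mapping: Mapping[str, str] = field(default_factory=_standard_code)

    def __post_init__(self) -> None:
        if len(self.mapping) != 64:
            raise ConfigurationError(
                f"genetic code must map all 64 codons, got {len(self.mapping)}"
            )
        n_sense = sum(1 for aa in self.mapping.values() if aa != "*")
        if n_sense != 61:
            raise ConfigurationError(f"expected 61 sense codons, got {n_sense}")

    def translate(self, codon: Codon) -> str:
        return self.mapping[codon.bases]

    def sense_codons(self) -> list[Codon]:
        return [Codon(c) for c, aa in sorted(self.mapping.items()) if aa != "*"]

    def codons_for(self, aa: str) -> list[Codon]:
        hits = [Codon(c) for c, a in sorted(self.mapping.items()) if a == aa]
        if not hits:
            raise InvalidInputError(f"no codon encodes {aa!r}")
        return hits


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative codon usage; unit = fraction of synonymous usage (sums to ~1 per residue)."""

    usage: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = {c: v for c, v in self.usage.items() if v < 0}
        if bad:
            raise ConfigurationError(f"negative usage values: {bad}")

    def __getitem__(self, codon: Codon) -> float:
        try:
            return self.usage[codon.bases]
        except KeyError:
            raise ConfigurationError(f"no usage entry for codon {codon}") from None


@dataclass(frozen=True)
class MutationKey:
    """One amino-acid substitution at one position (BRAF author numbering)."""

    position: int
    wt_aa: str
    mut_aa: str

    def __post_init__(self) -> None:
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in AMINO_ACIDS:
                raise InvalidInputError(f"not a standard amino acid: {aa!r}")

    @property
    def is_self(self) -> bool:
        return self.wt_aa == self.mut_aa

    @classmethod
    def parse(cls, label: str) -> "MutationKey":
        m = re.match(r"^([A-Y])(\d+)([A-Y])$", label.strip())
        if not m:
            raise InvalidInputError(f"cannot parse mutation label {label!r}")
        return cls(position=int(m.group(2)), wt_aa=m.group(1), mut_aa=m.group(3))

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


@dataclass(frozen=True)
class AccessibilityRecord:
    """Mutational accessibility of one substitution from its reference codon."""

    mutation: MutationKey
    wt_codon: Codon
    min_substitutions: int
    minimal_codons: frozenset[Codon]
    usage_delta: float


def _check_sense(wt_codon: Codon, target_aa: str, code: GeneticCode) -> None:
    if code.translate(wt_codon) == "*":
        raise InvalidInputError(f"{wt_codon} is a stop codon, not a sense codon")
    if target_aa not in AMINO_ACIDS:
        raise InvalidInputError(f"target must be one of the 20 amino acids, got {target_aa!r}")


def min_nt_substitutions(wt_codon: Codon, target_aa: str, code: GeneticCode | None = None) -> int:
    """Minimum number of base changes turning ``wt_codon`` into any codon of ``target_aa``.

    Ranges 0 (synonymous at the protein level, i.e. the target is the codon's
    own residue) to 3.
    """
    code = code or GeneticCode()
    _check_sense(wt_codon, target_aa, code)
    return min(wt_codon.hamming(c) for c in code.codons_for(target_aa))


def minimal_mutant_codons(
    wt_codon: Codon, target_aa: str, code: GeneticCode | None = None
) -> frozenset[Codon]:
    """All codons of ``target_aa`` at exactly the minimal Hamming distance."""
    code = code or GeneticCode()
    _check_sense(wt_codon, target_aa, code)
    candidates = code.codons_for(target_aa)
    dmin = min(wt_codon.hamming(c) for c in candidates)
    return frozenset(c for c in candidates if wt_codon.hamming(c) == dmin)


def usage_delta(
    wt_codon: Codon,
    target_aa: str,
    code: GeneticCode | None = None,
    usage: CodonUsageTable | None = None,
) -> float:
    """Usage(mutant codon) − usage(wt codon) for the chosen minimal mutant codon.

    Among minimally distant mutant codons the one with maximal usage is taken
    (ties on usage broken alphabetically for determinism): the most accessible
    high-expression outcome.
    """
    code = code or GeneticCode()
    usage = usage or load_human_codon_usage()
    chosen = select_mutant_codon(wt_codon, target_aa, code, usage)
    return usage[chosen] - usage[wt_codon]


def select_mutant_codon(
    wt_codon: Codon, target_aa: str, code: GeneticCode, usage: CodonUsageTable
) -> Codon:
    minimal = minimal_mutant_codons(wt_codon, target_aa, code)
    return max(sorted(minimal, key=lambda c: c.bases), key=lambda c: usage[c])


def accessibility_record(
    mutation: MutationKey,
    wt_codon: Codon,
    code: GeneticCode | None = None,
    usage: CodonUsageTable | None = None,
) -> AccessibilityRecord:
    code = code or GeneticCode()
    usage = usage or load_human_codon_usage()
    if code.translate(wt_codon) != mutation.wt_aa:
        raise ConfigurationError(
            f"reference codon {wt_codon} encodes {code.translate(wt_codon)}, "
            f"not the wild-type residue {mutation.wt_aa} of {mutation}"
        )
    return AccessibilityRecord(
        mutation=mutation,
        wt_codon=wt_codon,
        min_substitutions=min_nt_substitutions(wt_codon, mutation.mut_aa, code),
        minimal_codons=minimal_mutant_codons(wt_codon, mutation.mut_aa, code),
        usage_delta=usage_delta(wt_codon, mutation.mut_aa, code, usage),
    )


def accessibility_table(
    reference_codons: Mapping[int, Codon],
    code: GeneticCode | None = None,
    usage: CodonUsageTable | None = None,
    targets: Iterable[str] = AMINO_ACIDS,
) -> list[AccessibilityRecord]:
    """AccessibilityRecords for every position × target substitution (incl. self)."""
    code = code or GeneticCode()
    usage = usage or load_human_codon_usage()
    records = []
    for position in sorted(reference_codons):
        wt_codon = reference_codons[position]
        wt_aa = code.translate(wt_codon)
        for target in targets:
            key = MutationKey(position=position, wt_aa=wt_aa, mut_aa=target)
            records.append(accessibility_record(key, wt_codon, code, usage))
    return records


def _data_lines(name: str) -> list[list[str]]:
    text = resources.files("brafscan.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows[1:]  # drop header


def load_human_codon_usage() -> CodonUsageTable:
    """Bundled human codon-usage table (fraction of synonymous usage)."""
    usage = {codon: float(frac) for codon, _aa, frac in _data_lines("codon_usage_human.tsv")}
    return CodonUsageTable(usage=usage)


def load_reference_codons() -> dict[int, Codon]:
    """Bundled reference codons for the 14 analysed BRAF pocket positions."""
    return {int(pos): Codon(codon) for pos, codon in _data_lines("reference_codons_braf.tsv")}
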