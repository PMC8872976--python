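"""Combinatorial phenotype definitions and case/control assignment.

A phenotype is the cardinal-symptom requirement plus any subset of five
add-on diagnostic components; all 2^5 = 32 subsets are enumerated. Cases
endorse the cardinal item and every listed component; a participant is a
control as soon as one required element is explicitly not endorsed, so
controls are not screened against partial endorsement. Rows that cannot be
resolved either way because of missing responses are set to missing.
Exclusions (e.g. screening for other disorders) override case/control
status but are applied *after* the sample prevalence is computed, matching
the convention that population prevalence equals the pre-exclusion sample
prevalence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .simgen import COMPONENT_NAMES, ComponentTable

__all__ = [
    "PhenotypeDefinition",
    "CaseControlAssignment",
    "PhenotypePair",
    "CASE",
    "CONTROL",
    "MISSING",
    "EXCLUDED",
    "enumerate_phenotypes",
    "assign_case_control",
    "component_pairs",
]

# status codes (int8 vector)
CASE = 2
CONTROL = 1
MISSING = 0
EXCLUDED = -1


class PhenotypeError(ValueError):
    """Invalid phenotype definition or degenerate assignment."""


def _display(component: str) -> str:
    return component[:1].upper() + component[1:]


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A subset of add-on components; the cardinal requirement is implicit."""

    components: Tuple[str, ...]

    @property
    def name(self) -> str:
        return " + ".join(["Cardinal"] + [_display(c) for c in self.components])

    @property
    def enrichment(self) -> int:
        """1 + number of add-on components (cardinal-only phenotype is level 1)."""
        return 1 + len(self.components)

    def required_columns(self) -> Tuple[str, ...]:
        return ("cardinal",) + self.components


def enumerate_phenotypes(
    component_names: Sequence[str] = COMPONENT_NAMES,
) -> List[PhenotypeDefinition]:
    """All subsets of the component list, ordered by enrichment then name.

    Five components yield the full grid of 32 definitions.
    """
    names = tuple(component_names)
    if len(set(names)) != len(names):
        raise PhenotypeError("component labels must be unique")
    defs = []
    for r in range(len(names) + 1):
        for combo in itertools.combinations(names, r):
            defs.append(PhenotypeDefinition(components=combo))
    defs.sort(key=lambda d: (d.enrichment, tuple(sorted(d.components))))
    return defs


@dataclass
class CaseControlAssignment:
    """Per-individual status vector plus the counts and prevalence metadata."""

    definition: PhenotypeDefinition
    status: np.ndarray
    n_cases: int
    n_controls: int
    sample_prevalence_pre_exclusion: float

    @property
    def degenerate(self) -> bool:
        return self.n_cases == 0 or self.n_controls == 0

    @property
    def K(self) -> float:
        """Population prevalence under the sample-prevalence assumption."""
        return self.sample_prevalence_pre_exclusion


def assign_case_control(
    table: ComponentTable, defn: PhenotypeDefinition
) -> CaseControlAssignment:
    """Apply the case/control rule for one definition.

    case    - cardinal and every listed component endorsed (observed 1s);
    control - at least one required element explicitly not endorsed;
    missing - neither resolvable because of missing responses;
    excluded overrides everything, but only after the pre-exclusion sample
    prevalence is recorded.
    """
    required = defn.required_columns()
    missing_cols = [c for c in required if c not in table.values.columns]
    if missing_cols:
        raise PhenotypeError(f"component table lacks columns {missing_cols}")
    vals = table.values[list(required)].to_numpy(dtype=np.float64)

    all_one = np.all(vals == 1.0, axis=1)
    any_zero = np.any(vals == 0.0, axis=1)

    status = np.full(table.n, MISSING, dtype=np.int8)
    status[all_one] = CASE
    status[any_zero] = CONTROL  # any explicit non-endorsement wins over NaN

    pre_cases = int((status == CASE).sum())
    pre_controls = int((status == CONTROL).sum())
    denom = pre_cases + pre_controls
    prevalence = pre_cases / denom if denom else float("nan")

    status[np.asarray(table.excluded, dtype=bool)] = EXCLUDED
    return CaseControlAssignment(
        definition=defn,
        status=status,
        n_cases=int((status == CASE).sum()),
        n_controls=int((status == CONTROL).sum()),
        sample_prevalence_pre_exclusion=prevalence,
    )


@dataclass(frozen=True)
class PhenotypePair:
    """Two definitions differing by exactly one added component."""

    base: PhenotypeDefinition
    enriched: PhenotypeDefinition
    added_component: str

    @property
    def base_enrichment(self) -> int:
        return self.base.enrichment


def component_pairs(definitions: Iterable[PhenotypeDefinition]) -> List[PhenotypePair]:
    """All (base, base + one component) pairs from a complete grid.

    On the full five-component grid this yields 80 pairs, 16 per component,
    which group into 25 (component x base-enrichment) attribution cells.
    """
    defs = list(definitions)
    by_set = {frozenset(d.components): d for d in defs}
    all_components = sorted({c for d in defs for c in d.components})
    expected = 2 ** len(all_components)
    if len(by_set) != expected:
        raise PhenotypeError(
            f"definition list incomplete: {len(by_set)} of {expected} subsets present"
        )
    pairs = []
    for comp in all_components:
        others = [c for c in all_components if c != comp]
        for r in range(len(others) + 1):
            for combo in itertools.combinations(others, r):
                base = by_set[frozenset(combo)]
                enriched = by_set[frozenset(combo) | {comp}]
                pairs.append(
                    PhenotypePair(base=base, enriched=enriched, added_component=comp)
                )
    pairs.sort(
        key=lambda p: (p.added_component, p.base_enrichment, tuple(sorted(p.base.components)))
    )
    return pairs
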