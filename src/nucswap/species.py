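"""Combinatorial enumeration of labeled nucleosome species.

Two nucleosome pools are mixed 1:1.  The *DNA-labeled* pool carries a
Cy3/Cy5 FRET pair on the nucleosomal DNA plus a biotin for surface
immobilization; only these molecules are observable.  The *histone-labeled*
pool carries Cy5.5 on H2B with labeling efficiency ``F`` per H2A-H2B copy
and is free in solution.  Each nucleosome has two H2A-H2B slots: the
entry-proximal and the entry-distal dimer.

Species labels follow the field's bookkeeping for this experiment:

========  =============  ========================  =======================
label     pool           proximal slot labeled?    distal slot labeled?
========  =============  ========================  =======================
A         dna_labeled    no                        no
b         dna_labeled    yes                       no
e         dna_labeled    no                        yes
B'        dna_labeled    yes                       yes
C         histone        yes                       yes
d         histone        yes                       no
f         histone        no                        yes
D'        histone        no                        no
========  =============  ========================  =======================

``B`` is the union b ∪ e (exactly one slot labeled, DNA pool) and ``D`` the
union d ∪ f (exactly one slot labeled, histone pool).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict


class Pool(str, Enum):
    DNA_LABELED = "dna_labeled"
    HISTONE_LABELED = "histone_labeled"


@dataclass(frozen=True)
class LabeledSpecies:
    """One concrete labeling state of a nucleosome."""

    pool: Pool
    proximal_labeled: bool
    distal_labeled: bool
    label: str

    @property
    def observable(self) -> bool:
        """Only DNA-labeled (immobilizable) nucleosomes are imaged."""
        return self.pool is Pool.DNA_LABELED


#: The ten enumerable species labels.  A/b/e/B' partition the DNA pool by
#: slot labeling state; C/d/f/D' partition the histone pool.  B and D are
#: the aggregate singly-labeled species.
SPECIES: Dict[str, LabeledSpecies] = {
    "A": LabeledSpecies(Pool.DNA_LABELED, False, False, "A"),
    "b": LabeledSpecies(Pool.DNA_LABELED, True, False, "b"),
    "e": LabeledSpecies(Pool.DNA_LABELED, False, True, "e"),
    "B'": LabeledSpecies(Pool.DNA_LABELED, True, True, "B'"),
    "C": LabeledSpecies(Pool.HISTONE_LABELED, True, True, "C"),
    "d": LabeledSpecies(Pool.HISTONE_LABELED, True, False, "d"),
    "f": LabeledSpecies(Pool.HISTONE_LABELED, False, True, "f"),
    "D'": LabeledSpecies(Pool.HISTONE_LABELED, False, False, "D'"),
}

#: Aggregate labels: B = exactly-one-slot-labeled DNA pool, D likewise for
#: the histone pool.
AGGREGATES = {"B": ("b", "e"), "D": ("d", "f")}

ALL_LABELS = tuple(SPECIES) + tuple(AGGREGATES)  # 10 distinct labels

_SUM_TOL = 1e-9


@dataclass
class SpeciesMixture:
    """Mole fractions of the concrete species plus the mix parameters.

    Fractions are over the *total* nucleosome population (both pools).
    ``x`` is the mole fraction of aggregate species B (= b + e).
    """

    mole_fraction: Dict[str, float]
    F: float

    def __post_init__(self) -> None:
        for lab, frac in self.mole_fraction.items():
            if lab not in SPECIES:
                raise ValueError(f"unknown species label {lab!r}")
            if not -_SUM_TOL <= frac <= 1 + _SUM_TOL:
                raise ValueError(f"fraction of {lab!r} outside [0,1]: {frac}")
        total = sum(self.mole_fraction.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"species fractions sum to {total}, not 1")

    def __getitem__(self, label: str) -> float:
        if label in AGGREGATES:
            return sum(self.mole_fraction.get(p, 0.0) for p in AGGREGATES[label])
        return self.mole_fraction.get(label, 0.0)

    @property
    def x(self) -> float:
        """Mole fraction of aggregate species B."""
        return self["B"]


def enumerate_initial_mixture(F: float) -> SpeciesMixture:
    """Species mixture at t = 0 for a 1:1 mix of the two pools.

    Each H2A-H2B slot of a histone-pool nucleosome is labeled independently
    with probability ``F``, so within the histone half of the population the
    both/one/neither-labeled fractions are F², 2F(1−F), (1−F)².  The DNA
    pool starts entirely unlabeled (species A).

    Parameters
    ----------
    F : float
        H2A-H2B labeling efficiency, in [0, 1].
    """
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"labeling efficiency F must be in [0,1], got {F}")
    fractions = {
        "A": 0.5,
        "b": 0.0,
        "e": 0.0,
        "B'": 0.0,
        "C": 0.5 * F**2,
        "d": 0.5 * F * (1.0 - F),
        "f": 0.5 * F * (1.0 - F),
        "D'": 0.5 * (1.0 - F) ** 2,
    }
    return SpeciesMixture(mole_fraction=fractions, F=F)
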