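"""Published helical parameters of Abeta40 fibril polymorphs.

Refined twist/rise/symmetry/handedness for the three rapidly twisting
polymorphs characterized at high resolution (deposited as PDB 11EN, 11EO,
11EP), the related RT-Abeta40(C1)' class, and the previously described
slowly twisting polymorphs they are compared against.  ``crossover_nm``
holds the printed integer-nanometre cross-over distance for cross-checking;
all package computations derive the cross-over from twist and rise.
"""

from __future__ import annotations

from .helix import HelicalParams

__all__ = ["RAPIDLY_TWISTING", "REFERENCE_POLYMORPHS", "ALL_POLYMORPHS", "by_name"]

#: The rapidly twisting polymorphs (cross-over distances near 25 nm).
RAPIDLY_TWISTING: list[HelicalParams] = [
    HelicalParams(name="RT-Ab40(2_1)", twist=-181.75, rise=2.34, symmetry="pseudo-2_1",
                  handedness="right", molecules_per_repeat=1, crossover_nm=24),
    HelicalParams(name="RT-Ab40(C2)", twist=-3.55, rise=4.69, symmetry="C2",
                  handedness="left", molecules_per_repeat=2, crossover_nm=24),
    HelicalParams(name="RT-Ab40(C1)", twist=-5.24, rise=9.40, symmetry="C1",
                  handedness="right", molecules_per_repeat=2, crossover_nm=32),
    HelicalParams(name="RT-Ab40(C1)'", twist=-1.96, rise=4.76, symmetry="C1",
                  handedness="undetermined", molecules_per_repeat=2, crossover_nm=44),
]

#: Previously described slowly twisting Abeta40 polymorphs (by PDB code).
REFERENCE_POLYMORPHS: list[HelicalParams] = [
    HelicalParams(name="8OT4", twist=181.18, rise=2.38, symmetry="pseudo-2_1",
                  handedness="right", molecules_per_repeat=1, crossover_nm=36),
    HelicalParams(name="9IIO", twist=179.2, rise=2.45, symmetry="pseudo-2_1",
                  handedness="left", molecules_per_repeat=1, crossover_nm=55),
    HelicalParams(name="8QN6", twist=-0.79, rise=4.87, symmetry="C2",
                  handedness="right", molecules_per_repeat=2, crossover_nm=111),
    HelicalParams(name="8QN7", twist=179.53, rise=2.44, symmetry="pseudo-2_1",
                  handedness="right", molecules_per_repeat=1, crossover_nm=93),
    HelicalParams(name="8FF2", twist=181.17, rise=2.44, symmetry="pseudo-2_1",
                  handedness="right", molecules_per_repeat=1, crossover_nm=38),
    HelicalParams(name="6SHS", twist=181.0, rise=2.41, symmetry="pseudo-2_1",
                  handedness="right", molecules_per_repeat=1, crossover_nm=43),
    HelicalParams(name="8OT1", twist=-0.782, rise=4.763, symmetry="C2",
                  handedness="left", molecules_per_repeat=2, crossover_nm=110),
    HelicalParams(name="8OT3", twist=179.526, rise=2.372, symmetry="pseudo-2_1",
                  handedness="left", molecules_per_repeat=1, crossover_nm=90),
    HelicalParams(name="8FF3", twist=179.75, rise=2.44, symmetry="pseudo-2_1",
                  handedness="undetermined", molecules_per_repeat=1, crossover_nm=176),
    HelicalParams(name="6W0O", twist=-180.34, rise=2.45, symmetry="pseudo-2_1",
                  handedness="left", molecules_per_repeat=1, crossover_nm=130),
]

ALL_POLYMORPHS: list[HelicalParams] = RAPIDLY_TWISTING + REFERENCE_POLYMORPHS


def by_name(name: str) -> HelicalParams:
    for p in ALL_POLYMORPHS:
        if p.name.lower() == name.lower():
            return p
    raise KeyError(f"unknown polymorph {name!r}")
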