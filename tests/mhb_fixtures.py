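"""Constructed mid-hindbrain-boundary-style fixtures for the selection screen.

Synthetic stand-ins for the original validated rule sets, which are not
distributed with this package: nine 4-species Boolean models (Otx2, Gbx2
transcription factors; Fgf8, Wnt1 secreted) that hold a boundary-like
expression pattern across a 6-compartment row, built around the mutual
Otx2/Gbx2 inhibition and the mutual intercompartmental Fgf8/Wnt1
maintenance.  The pattern: Otx2 in compartments 1-3, Gbx2 in 4-6, Wnt1 at
the Otx2 side of the boundary (compartment 3), Fgf8 at the Gbx2 side
(compartment 4).
"""

import numpy as np

from hillcube import CompartmentSpec, parse_boolean_equations

SPECIES = ("Otx2", "Gbx2", "Wnt1", "Fgf8")
N_COMPARTMENTS = 6
SECRETED = frozenset({"Fgf8", "Wnt1"})

COMPARTMENT_SPEC = CompartmentSpec(N_COMPARTMENTS, SECRETED)

#: Compartments × species on/off targets (species order as in SPECIES).
MHB_PATTERN = np.array(
    [
        [1, 0, 0, 0],
        [1, 0, 0, 0],
        [1, 0, 1, 0],
        [0, 1, 0, 1],
        [0, 1, 0, 0],
        [0, 1, 0, 0],
    ],
    dtype=bool,
)

_VALID_EQUATIONS = [
    # base: mutual TF inhibition, mutual secreted maintenance
    """Otx2 = ~Gbx2
       Gbx2 = ~Otx2
       Wnt1 = Otx2 && Fgf8
       Fgf8 = Gbx2 && Wnt1""",
    """Otx2 = ~Gbx2
       Gbx2 = ~Otx2
       Wnt1 = Otx2 && Fgf8 && ~Gbx2
       Fgf8 = Gbx2 && Wnt1""",
    """Otx2 = ~Gbx2
       Gbx2 = ~Otx2
       Wnt1 = Otx2 && Fgf8
       Fgf8 = Gbx2 && Wnt1 && ~Otx2""",
    """Otx2 = ~Gbx2
       Gbx2 = ~Otx2
       Wnt1 = Otx2 && Fgf8 && ~Gbx2
       Fgf8 = Gbx2 && Wnt1 && ~Otx2""",
    """Otx2 = Otx2 && ~Gbx2
       Gbx2 = ~Otx2
       Wnt1 = Otx2 && Fgf8
       Fgf8 = Gbx2 && Wnt1""",
    """Otx2 = ~Gbx2
       Gbx2 = Gbx2 && ~Otx2
       Wnt1 = Otx2 && Fgf8
       Fgf8 = Gbx2 && Wnt1""",
    """Otx2 = ~Gbx2
       Gbx2 = ~Otx2
       Wnt1 = (Otx2 || Wnt1) && Fgf8
       Fgf8 = Gbx2 && Wnt1""",
    """Otx2 = ~Gbx2
       Gbx2 = ~Otx2
       Wnt1 = Otx2 && Fgf8
       Fgf8 = (Gbx2 || Fgf8) && Wnt1""",
    """Otx2 = Otx2 && ~Gbx2
       Gbx2 = Gbx2 && ~Otx2
       Wnt1 = Otx2 && Fgf8
       Fgf8 = Gbx2 && Wnt1""",
]


def valid_models():
    """The nine constructed pattern-holding models, species order fixed."""
    models = []
    for text in _VALID_EQUATIONS:
        model = parse_boolean_equations(text)
        assert model.species == SPECIES
        models.append(model)
    return models
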