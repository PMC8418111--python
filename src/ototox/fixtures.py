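"""Small literature-derived compound fixture set.

A handful of compounds with documented inner-ear outcomes, usable as a
tiny illustrative reference set and to exercise the SMILES → fingerprint
path on real chemistry (including the awkward cases: cisplatin is a
multi-fragment platinum complex whose circular fingerprint is nearly
empty).  SMILES are PubChem-derived.  This set is far too small to train a
useful model — the synthetic generator provides populations at realistic
size — but it keeps every example in the documentation runnable on real
structures.
"""

from __future__ import annotations

from .chem_io import CompoundSet, Label, parse_compound

__all__ = ["LITERATURE_COMPOUNDS", "literature_reference_sets"]

# name -> (SMILES, label)
LITERATURE_COMPOUNDS: dict[str, tuple[str, Label]] = {
    # aminoglycoside antibiotics: classic cochleotoxins
    "kanamycin": (
        "NCC1OC(OC2C(N)CC(N)C(OC3OC(CO)C(O)C(N)C3O)C2O)C(N)C(O)C1O",
        Label.OTOTOXIN,
    ),
    "gentamicin": (
        "CC(NC)C1CCC(N)C(OC2C(N)CC(N)C(OC3OCC(C)(O)C(NC)C3O)C2O)O1",
        Label.OTOTOXIN,
    ),
    # platinum chemotherapy: multi-fragment metal complex, low-information fp
    "cisplatin": ("N.N.Cl[Pt]Cl", Label.OTOTOXIN),
    # antimalarial with reported hair-cell toxicity
    "chloroquine": ("CCN(CC)CCCC(C)Nc1ccnc2cc(Cl)ccc12", Label.OTOTOXIN),
    # vinca alkaloid, hair-cell toxic in lateral-line assays
    "vindesine": (
        "CCC1(O)CC2CC(c3[nH]c4ccccc4c3CCN(C2)C1)(C(=O)OC)"
        "c1cc2c(cc1OC)N(C)C1C2(CC2)C(O)C(O)(C(N)=O)C1CC2",
        Label.OTOTOXIN,
    ),
    # dihydropyridine antihypertensive, hair-cell toxic in lateral-line assays
    "isradipine": (
        "CC(C)OC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1cccc2nonc12",
        Label.OTOTOXIN,
    ),
    # flavonoid antioxidant, tested ear-safe in lateral-line assays
    "dihydromyricetin": (
        "O=C1c2c(O)cc(O)cc2OC(c2cc(O)c(O)c(O)c2)C1O",
        Label.NON_OTOTOXIN,
    ),
}


def literature_reference_sets() -> tuple[CompoundSet, CompoundSet]:
    """The fixture compounds as (ototoxins, non_ototoxins) CompoundSets."""
    otos, nons = [], []
    for name, (smiles, label) in LITERATURE_COMPOUNDS.items():
        c = parse_compound(smiles, name, label, source="fixture")
        (otos if label is Label.OTOTOXIN else nons).append(c)
    return (
        CompoundSet(otos, name="literature-ototoxins"),
        CompoundSet(nons, name="literature-non-ototoxins"),
    )
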