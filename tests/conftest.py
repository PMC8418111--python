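import pytest

from ototox.chem_io import Compound, CompoundSet, Label
from ototox.fingerprints import Fingerprint, FingerprintParams
from ototox.synthetic import SyntheticSpec, generate_population

SMALL_PARAMS = FingerprintParams(n_bits=64)


def make_synth_compound(
    cid: str, bits, label: Label, params: FingerprintParams = SMALL_PARAMS
) -> Compound:
    """A compound with an injected fingerprint (no SMILES parsing)."""
    fp = Fingerprint(bits=frozenset(bits), n_bits=params.n_bits, params=params)
    return Compound(
        id=cid,
        smiles_raw="",
        smiles_canonical=f"synthetic:{cid}",
        label=label,
        source="test",
        fingerprint=fp,
    )


@pytest.fixture(scope="session")
def separable_population():
    """Near-separable synthetic population at the default study shape."""
    spec = SyntheticSpec(separation=0.9, flip_noise=0.05, seed=0)
    otos, nons, truth = generate_population(spec)
    return otos, nons, truth


@pytest.fixture
def simple_smiles_dataset(tmp_path):
    """Two small labeled .smi files of real, easily separable chemotypes:
    aminoglycoside-like aliphatic polyols vs halogenated aromatics."""
    positives = [
        ("OCC(O)C(O)CO", "polyol-1"),
        ("OCC(O)C(O)C(O)CO", "polyol-2"),
        ("OCC(O)C(O)C(O)C(O)CO", "polyol-3"),
        ("NCC(O)C(O)CO", "aminopolyol-1"),
        ("NCC(O)C(O)C(O)CO", "aminopolyol-2"),
        ("NCC(O)C(N)C(O)CO", "aminopolyol-3"),
        ("OCC(N)C(O)C(O)CO", "aminopolyol-4"),
        ("NCC(O)C(O)C(O)C(O)CO", "aminopolyol-5"),
        ("OCC(O)C(N)C(O)C(O)CO", "aminopolyol-6"),
        ("NCC(N)C(O)C(O)CO", "aminopolyol-7"),
    ]
    negatives = [
        ("Clc1ccccc1", "haloarene-1"),
        ("Clc1ccc(Cl)cc1", "haloarene-2"),
        ("Brc1ccccc1", "haloarene-3"),
        ("Clc1cccc(Br)c1", "haloarene-4"),
        ("Fc1ccccc1", "haloarene-5"),
        ("Clc1ccc(F)cc1", "haloarene-6"),
        ("Brc1ccc(Br)cc1", "haloarene-7"),
        ("Fc1ccc(Cl)cc1", "haloarene-8"),
        ("Clc1ccccc1Cl", "haloarene-9"),
        ("Brc1ccccc1F", "haloarene-10"),
    ]
    oto_path = tmp_path / "ototoxins.smi"
    non_path = tmp_path / "non_ototoxins.smi"
    oto_path.write_text(
        "".join(f"{smi}\t{cid}\n" for smi, cid in positives), encoding="utf-8"
    )
    non_path.write_text(
        "".join(f"{smi}\t{cid}\n" for smi, cid in negatives), encoding="utf-8"
    )
    return oto_path, non_path


@pytest.fixture
def labeled_compound_sets(simple_smiles_dataset):
    from ototox.chem_io import read_compound_file

    oto_path, non_path = simple_smiles_dataset
    otos, _ = read_compound_file(oto_path, label=Label.OTOTOXIN)
    nons, _ = read_compound_file(non_path, label=Label.NON_OTOTOXIN)
    return otos, nons
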