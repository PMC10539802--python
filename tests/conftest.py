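"""Shared fixtures: reference stats, synthetic entries, and mmCIF builders."""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import gemmi
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")

from aroshift.geometry import StructureEnsemble, StructureModel, ModelResidue
from aroshift.reference_stats import ReferenceStats
from aroshift.synthetic import AmideTarget, SyntheticSpec, write_entry


@pytest.fixture(scope="session")
def stats() -> ReferenceStats:
    return ReferenceStats.default()


@pytest.fixture(scope="session")
def mixed_spec() -> SyntheticSpec:
    """One entry with all four aromatic types and planted amide geometries."""
    return SyntheticSpec(
        n_residues=14,
        aromatic_positions={3: "PHE", 6: "TRP", 9: "HIS", 12: "TYR"},
        amide_geometries={
            1: AmideTarget(3, 3.0, 0.0),
            2: AmideTarget(3, 4.0, 30.0),
            4: AmideTarget(6, 3.5, 20.0),
            5: AmideTarget(9, 3.4, 90.0),
            7: AmideTarget(6, 5.0, 70.0, ring_label="six"),
            10: AmideTarget(12, 4.5, 55.0),
        },
        n_models=3,
        coordinate_jitter_A=0.0,
        shift_noise_ppm=0.0,
        seed=42,
        entry_id="SYNMIX",
    )


@pytest.fixture(scope="session")
def mixed_entry(mixed_spec, stats, tmp_path_factory):
    """The mixed entry written to disk: structure.cif/shifts.str/restraints.str."""
    out = tmp_path_factory.mktemp("mixed_entry")
    return write_entry(mixed_spec, out, stats)


def make_gemmi_structure(
    name: str,
    chains: Dict[str, List[Tuple[str, int, List[Tuple[str, str, Tuple[float, float, float]]]]]],
    n_models: int = 1,
) -> gemmi.Structure:
    """Build a gemmi Structure from {chain: [(resname, seq, [(atom, element, xyz)])]}."""
    st = gemmi.Structure()
    st.name = name
    for m in range(1, n_models + 1):
        model = gemmi.Model(m)
        for chain_name, residues in chains.items():
            chain = gemmi.Chain(chain_name)
            for resname, seq, atoms in residues:
                res = gemmi.Residue()
                res.name = resname
                res.seqid = gemmi.SeqId(seq, " ")
                for aname, elem, xyz in atoms:
                    atom = gemmi.Atom()
                    atom.name = aname
                    atom.element = gemmi.Element(elem)
                    atom.pos = gemmi.Position(*xyz)
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    return st


def peptide_chain(n: int, x_off: float = 0.0, y_off: float = 0.0):
    """A minimal polyalanine chain description for make_gemmi_structure."""
    out = []
    for i in range(1, n + 1):
        x = x_off + 3.8 * i
        out.append((
            "ALA", i,
            [("N", "N", (x, y_off, 0.0)),
             ("CA", "C", (x + 1.2, y_off + 0.8, 0.0)),
             ("C", "C", (x + 2.4, y_off, 0.3)),
             ("O", "O", (x + 2.4, y_off + 1.2, 0.3))],
        ))
    return out


def rigid_transform_ensemble(
    ensemble: StructureEnsemble, rotation: np.ndarray, translation: np.ndarray
) -> StructureEnsemble:
    """Apply one rotation+translation to every atom of every model."""
    models = []
    for model in ensemble.models:
        residues = {}
        for key, res in model.residues.items():
            atoms = {
                name: rotation @ xyz + translation
                for name, xyz in res.atoms.items()
            }
            residues[key] = ModelResidue(res.chain, res.seq_id,
                                         res.residue_type, atoms)
        models.append(StructureModel(residues))
    return StructureEnsemble(ensemble.entry_id, models, ensemble.meta)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
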