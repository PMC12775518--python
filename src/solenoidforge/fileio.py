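"""File I/O: Cα PDB round-trips, FASTA, trajectory logs and run configs."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidInputError
from .evolution_engine import EvolutionConfig, GenerationRecord
from .repeat_sequences import RepeatSpec, SolenoidClass


def read_ca_pdb(path) -> tuple[np.ndarray, str]:
    """Cα coordinates and one-letter sequence from a PDB file.

    Conventions: first model, first chain, ATOM records only, altloc ''
    or 'A'.  Residue order follows the file.  Unknown residue names map
    to 'X'.
    """
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise InvalidInputError(f"no models in {path}")
    model = structure[0]
    if len(model) == 0:
        raise InvalidInputError(f"no chains in first model of {path}")
    chain = model[0]
    coords, letters = [], []
    for residue in chain:
        if residue.het_flag != "A":  # ATOM records only
            continue
        for atom in residue:
            if atom.name == "CA" and atom.altloc in ("\0", "", "A"):
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                info = gemmi.find_tabulated_residue(residue.name)
                one = info.one_letter_code.upper() if info else "X"
                letters.append(one if one.isalpha() else "X")
                break
    if not coords:
        raise InvalidInputError(f"no CA atoms found in {path}")
    return np.array(coords, dtype=float), "".join(letters)


_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_ca_pdb(path, coords: np.ndarray, sequence: str | None = None) -> None:
    """Write a Cα-only PDB file (chain A, three-decimal Å precision)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InvalidInputError(f"coords must be (n,3), got {coords.shape}")
    n = coords.shape[0]
    if sequence is None:
        sequence = "A" * n
    if len(sequence) != n:
        raise InvalidInputError("sequence length must match coordinate rows")
    structure = gemmi.Structure()
    structure.name = "design"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, (xyz, aa) in enumerate(zip(coords, sequence), start=1):
        residue = gemmi.Residue()
        residue.name = _ONE_TO_THREE.get(aa, "UNK")
        residue.seqid = gemmi.SeqId(i, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*xyz)
        atom.occ = 1.0
        atom.b_iso = 0.0
        residue.add_atom(atom)
        chain.add_residue(residue)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write (name, sequence) pairs as FASTA with 60-column wrapping."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]


def write_trajectory_jsonl(path, trajectory: Sequence[GenerationRecord]) -> None:
    """One JSON object per generation (append-safe log format)."""
    with open(path, "w") as fh:
        for rec in trajectory:
            fh.write(
                json.dumps(
                    {
                        "generation": rec.generation,
                        "best_fitness": rec.best_fitness,
                        "mean_fitness": rec.mean_fitness,
                        "fitness_std": rec.fitness_std,
                        "mean_plddt": rec.component_means[0],
                        "mean_solenoid_score": rec.component_means[1],
                        "best_unit": rec.best_candidate.unit.residues,
                        "best_sequence": rec.best_candidate.full_sequence,
                    }
                )
                + "\n"
            )


def trajectory_frame(trajectory: Sequence[GenerationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "generation": [r.generation for r in trajectory],
            "best_fitness": [r.best_fitness for r in trajectory],
            "mean_fitness": [r.mean_fitness for r in trajectory],
            "fitness_std": [r.fitness_std for r in trajectory],
            "mean_plddt": [r.component_means[0] for r in trajectory],
            "mean_solenoid_score": [r.component_means[1] for r in trajectory],
        }
    )


@dataclasses.dataclass
class RunConfig:
    """Serialisable description of one design run."""

    spec: RepeatSpec
    evolution: EvolutionConfig
    oracle: str = "mock"
    output_dir: str = "runs"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        spec_raw = dict(raw["spec"])
        if "length_band" in spec_raw:
            spec_raw["length_band"] = tuple(spec_raw["length_band"])
        if "target_class" in spec_raw:
            spec_raw["target_class"] = SolenoidClass(spec_raw["target_class"])
        return cls(
            spec=RepeatSpec(**spec_raw),
            evolution=EvolutionConfig(**raw.get("evolution", {})),
            oracle=raw.get("oracle", "mock"),
            output_dir=raw.get("output_dir", "runs"),
        )

    def to_yaml(self, path) -> None:
        spec_dict = dataclasses.asdict(self.spec)
        spec_dict["target_class"] = self.spec.target_class.value
        spec_dict["length_band"] = list(self.spec.length_band)
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "spec": spec_dict,
                    "evolution": dataclasses.asdict(self.evolution),
                    "oracle": self.oracle,
                    "output_dir": self.output_dir,
                },
                sort_keys=False,
            )
        )
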