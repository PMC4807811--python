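"""Readers and writers for the standard formats around the pipeline.

PDB in (Cα extraction with altloc/chain/range handling, Å converted to
nm on read), Cα-only PDB out for synthetic fixtures, TSV profiles and
matrices, significant-pair tables with an optional PyMOL-dialect stick
script, and JSON run manifests.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .enm import RESIDUE_MASSES, _DEFAULT_MASS, CaModel
from .descriptors import (CorrelationMatrix, DeformationProfile,
                          FluctuationProfile, SignificantPairSet)

__all__ = [
    "read_pdb_ca",
    "write_pdb_ca",
    "write_fasta",
    "write_profile_tsv",
    "write_correlation_tsv",
    "read_correlation_tsv",
    "write_pairs_tsv",
    "write_pymol_sticks",
    "run_manifest",
]

ANGSTROM_PER_NM = 10.0


def read_pdb_ca(
    path,
    chains: str | list[str] | None = None,
    residue_range: tuple[int, int] | None = None,
    model_index: int = 0,
    label: str | None = None,
    unit_masses: bool = False,
) -> CaModel:
    """Extract one Cα per residue from a PDB file into a CaModel.

    chains may be a single chain id, a list (several chains combined
    into one model, e.g. a biological assembly), or None for all.
    residue_range is inclusive of both endpoints in author numbering
    and applies per chain.  Altloc ambiguity resolves to the
    highest-occupancy conformer.  Coordinates are converted Å -> nm.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))
    models = list(structure)
    if model_index >= len(models):
        raise ValueError(f"model index {model_index} out of range")
    model = models[model_index]
    if chains is None:
        chain_ids = [c.id for c in model]
    elif isinstance(chains, str):
        chain_ids = [chains]
    else:
        chain_ids = list(chains)
    available = {c.id for c in model}
    missing = [c for c in chain_ids if c not in available]
    if missing:
        raise ValueError(f"chains {missing} not found (have {sorted(available)})")

    atoms, coords, masses = [], [], []
    no_ca: list[str] = []
    for cid in chain_ids:
        for res in model[cid]:
            het, resseq, icode = res.id
            if het.strip():
                continue  # water/ligand records are not Cα nodes
            if residue_range is not None and not (
                residue_range[0] <= resseq <= residue_range[1]
            ):
                continue
            if "CA" not in res:
                no_ca.append(f"{cid}/{resseq}{icode.strip()}")
                continue
            ca = res["CA"]
            if ca.is_disordered():
                ca = max(ca, key=lambda a: a.get_occupancy() or 0.0)
            atoms.append((cid, int(resseq), icode.strip(), res.get_resname()))
            coords.append(np.asarray(ca.get_coord(), dtype=float)
                          / ANGSTROM_PER_NM)
            masses.append(1.0 if unit_masses
                          else RESIDUE_MASSES.get(res.get_resname(),
                                                  _DEFAULT_MASS))
    if no_ca:
        raise ValueError(f"residues lacking a Cα atom: {', '.join(no_ca)}")
    if not atoms:
        raise ValueError("empty selection: no Cα atoms matched")
    return CaModel(
        atoms=atoms,
        coords=np.array(coords),
        masses=np.array(masses),
        label=label or path.stem,
    )


def write_pdb_ca(model: CaModel, path) -> None:
    """Write a Cα-only PDB file (nm converted back to Å)."""
    with open(path, "w") as fh:
        for serial, ((chain, resseq, icode, resname), xyz) in enumerate(
            zip(model.atoms, model.coords * ANGSTROM_PER_NM), start=1
        ):
            fh.write(
                f"ATOM  {serial:5d}  CA  {resname:<3s} {chain:1s}"
                f"{resseq:4d}{icode or ' ':1s}   "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}           C  \n"
            )
        fh.write("END\n")


def write_fasta(records: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n{seq}\n")


def _header(lines: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in lines.items())


def write_profile_tsv(
    model: CaModel,
    profile: FluctuationProfile | DeformationProfile,
    path,
    kind: str,
) -> None:
    """Per-residue profile TSV: chain, residue, raw and normalised value."""
    if isinstance(profile, FluctuationProfile):
        raw, norm = profile.raw, profile.values
        meta = {"profile": kind, "normalization": profile.normalization}
    else:
        raw, norm = profile.raw, profile.normalized
        meta = {"profile": kind, "normalization": "min-max [0,1]"}
    meta["structure"] = model.label
    df = pd.DataFrame({
        "chain": [a[0] for a in model.atoms],
        "residue": [a[1] for a in model.atoms],
        "icode": [a[2] for a in model.atoms],
        "resname": [a[3] for a in model.atoms],
        "raw": raw,
        "normalized": norm,
    })
    with open(path, "w") as fh:
        fh.write(_header(meta))
        df.to_csv(fh, sep="\t", index=False)


def write_correlation_tsv(corr: CorrelationMatrix, path,
                          label: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_header({"matrix": "dynamic cross-correlation",
                          "structure": label, "n": corr.n}))
        np.savetxt(fh, corr.values, delimiter="\t", fmt="%.10g")


def read_correlation_tsv(path) -> CorrelationMatrix:
    return CorrelationMatrix(values=np.loadtxt(path, delimiter="\t",
                                               comments="#"))


def write_pairs_tsv(pairs: SignificantPairSet, model: CaModel, path) -> None:
    rows = []
    for (i, j, c, dist), oid in zip(pairs.pairs, pairs.object_ids):
        rows.append({
            "i": i, "j": j,
            "residue_i": model.atoms[i][1], "residue_j": model.atoms[j][1],
            "C": c, "distance_nm": dist,
            "sign": "positive" if c >= 0 else "negative",
            "object": oid,
        })
    with open(path, "w") as fh:
        fh.write(_header({
            "pairs": "significant correlations",
            "structure": model.label,
            "percentile": pairs.percentile,
            "min_distance_nm": pairs.min_distance,
            "threshold": pairs.threshold,
            "percentile_rule": "nearest-rank on |C|, i<j",
            "distance_rule": "input-configuration Calpha distance, ties kept",
        }))
        pd.DataFrame(
            rows,
            columns=["i", "j", "residue_i", "residue_j", "C",
                     "distance_nm", "sign", "object"],
        ).to_csv(fh, sep="\t", index=False)


def write_pymol_sticks(pairs: SignificantPairSet, model: CaModel, path,
                       object_prefix: str = "corr") -> None:
    """Emit a PyMOL-dialect script drawing retained pairs as sticks,
    red for positive and blue for negative correlations."""
    with open(path, "w") as fh:
        fh.write(f"# significant correlations for {model.label}\n")
        fh.write("set dash_gap, 0\nset dash_radius, 0.08\n")
        for n, (i, j, c, _dist) in enumerate(pairs.pairs):
            ci, ri = model.atoms[i][0], model.atoms[i][1]
            cj, rj = model.atoms[j][0], model.atoms[j][1]
            name = f"{object_prefix}_{n}"
            fh.write(
                f"distance {name}, chain {ci} and resi {ri} and name CA, "
                f"chain {cj} and resi {rj} and name CA\n"
            )
            fh.write(f"color {'red' if c >= 0 else 'blue'}, {name}\n")
        fh.write(f"hide labels, {object_prefix}_*\n")


def run_manifest(config: dict, seed: int | None, out_dir) -> Path:
    """Write a JSON manifest (package version, config hash, seed)."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "package": "barreldyn",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": config,
    }
    out = Path(out_dir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(manifest, indent=2, default=str))
    return out
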