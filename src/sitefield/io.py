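"""File I/O: extended-XYZ configurations, TOML run configs, JSON outputs.

The extended-XYZ dialect used here carries the cell in the comment-line
``Lattice="ax ay az bx by bz cx cy cz"`` tag and per-atom columns
``species:S:1:pos:R:3:q_neutral:R:1:q_charged:R:1:molecule_id:I:1``.
The writer emits full-precision (repr) floats so write→read round-trips are
lossless.
"""

from __future__ import annotations

import hashlib
import json
import re
import tomllib
from pathlib import Path

import numpy as np

from . import __version__
from .core import MoleculeChargeSpec, PeriodicCell, SystemConfiguration
from .dsf import DSFParams
from .ewald import EwaldParams

PROPERTIES = "species:S:1:pos:R:3:q_neutral:R:1:q_charged:R:1:molecule_id:I:1"


class ExtxyzParseError(ValueError):
    pass


def write_extxyz(path, config: SystemConfiguration) -> None:
    idx = config.atom_index_in_molecule()
    qn = config.charge_spec.neutral_charges[idx]
    qc = config.charge_spec.charged_charges[idx]
    lat = " ".join(repr(float(x)) for x in config.cell.lattice_vectors.ravel())
    lines = [str(config.n_atoms),
             f'Lattice="{lat}" Properties={PROPERTIES} '
             f'net_charge={config.charge_spec.net_charge} '
             f'active_state={config.active_state}']
    for a in range(config.n_atoms):
        x, y, z = (float(v) for v in config.positions[a])
        lines.append(f"{config.elements[a]} {x!r} {y!r} {z!r} "
                     f"{float(qn[a])!r} {float(qc[a])!r} "
                     f"{int(config.molecule_index[a])}")
    Path(path).write_text("\n".join(lines) + "\n")


def _comment_fields(comment: str, path, lineno: int) -> dict:
    fields = {}
    for match in re.finditer(r'(\w+)=("([^"]*)"|\S+)', comment):
        key = match.group(1)
        fields[key] = match.group(3) if match.group(3) is not None else match.group(2)
    if "Lattice" not in fields:
        raise ExtxyzParseError(f"{path}:{lineno}: missing Lattice tag")
    return fields


def read_extxyz(path) -> SystemConfiguration:
    text = Path(path).read_text().splitlines()
    if not text:
        raise ExtxyzParseError(f"{path}: empty file")
    try:
        n_atoms = int(text[0].strip())
    except ValueError as exc:
        raise ExtxyzParseError(f"{path}:1: bad atom count {text[0]!r}") from exc
    if n_atoms == 0:
        raise ExtxyzParseError(f"{path}: configuration has no atoms")
    fields = _comment_fields(text[1], path, 2)
    lat_tokens = fields["Lattice"].split()
    if len(lat_tokens) != 9:
        raise ExtxyzParseError(
            f"{path}:2: Lattice needs 9 numbers, got {len(lat_tokens)}")
    try:
        lattice = np.array([float(t) for t in lat_tokens]).reshape(3, 3)
    except ValueError as exc:
        bad = next(t for t in lat_tokens if not _is_float(t))
        raise ExtxyzParseError(f"{path}:2: bad lattice token {bad!r}") from exc

    elements, pos, qn, qc, mol = [], [], [], [], []
    for lineno, line in enumerate(text[2:2 + n_atoms], start=3):
        toks = line.split()
        if len(toks) != 7:
            raise ExtxyzParseError(
                f"{path}:{lineno}: expected 7 columns "
                f"(species x y z q_neutral q_charged molecule_id), got {len(toks)}")
        elements.append(toks[0])
        try:
            pos.append([float(t) for t in toks[1:4]])
            qn.append(float(toks[4]))
            qc.append(float(toks[5]))
            mol.append(int(toks[6]))
        except ValueError as exc:
            raise ExtxyzParseError(f"{path}:{lineno}: bad numeric token") from exc
    if len(elements) != n_atoms:
        raise ExtxyzParseError(f"{path}: fewer atom lines than the declared {n_atoms}")

    mol = np.array(mol)
    first = mol == mol[0]
    spec = MoleculeChargeSpec(
        neutral_charges=np.array(qn)[first],
        charged_charges=np.array(qc)[first],
        net_charge=float(fields.get("net_charge", np.sum(np.array(qc)[first]))),
    )
    active = int(fields.get("active_state", -1))
    return SystemConfiguration(PeriodicCell(lattice), np.array(pos), elements,
                               mol, spec, active_state=active)


def _is_float(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def load_run_config(path) -> dict:
    """TOML run configuration with flat keys mirroring the parameter types."""
    with open(path, "rb") as handle:
        raw = tomllib.load(handle)
    known = {"method", "ewald", "dsf", "seed", "output", "verbosity", "md"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return raw


def params_from_config(cfg: dict):
    method = cfg.get("method", "dsf")
    if method == "ewald":
        return method, EwaldParams(**cfg.get("ewald", {}))
    if method == "dsf":
        return method, DSFParams(**cfg.get("dsf", {}))
    raise ValueError(f"unknown method {method!r}")


def write_json_output(path, payload: dict, config_like=None, seed=None) -> None:
    """JSON with provenance: code version, config hash and seed."""
    meta = {"sitefield_version": __version__}
    if config_like is not None:
        digest = hashlib.sha256(
            json.dumps(config_like, sort_keys=True, default=str).encode()).hexdigest()
        meta["config_sha256"] = digest[:16]
    if seed is not None:
        meta["seed"] = seed
    out = {"meta": meta, **payload}
    Path(path).write_text(json.dumps(out, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
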