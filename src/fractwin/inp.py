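"""A documented subset of the Abaqus/CAE input-deck (.inp) dialect.

Sections handled: *NODE, *ELEMENT (C3D4/C3D10), *ELSET, *NSET,
*MATERIAL/*ELASTIC, *SOLID SECTION, *BOUNDARY, *AMPLITUDE, *CLOAD.
Ids are 1-based in the deck and 0-based in memory. Floats are written with
17 significant digits so read(write(X)) reproduces X exactly.

Conventions of this dialect:
- element sets ``REGION_<NAME>`` carry the region labels; element sets
  ``MAT_<k>`` group elements sharing an exact (E, nu) pair, each with a
  matching *MATERIAL/*ELASTIC/*SOLID SECTION block;
- the *BOUNDARY block fixes translations U1..U3 ("1, 3") on a node set;
- *AMPLITUDE tables hold the TOTAL force component over the cycle; the
  *CLOAD per-node magnitude is 1/n over the target set, i.e. the total is
  split equally across the loaded nodes.
"""

from __future__ import annotations

import numpy as np

from .fem import BoundaryCondition, LoadCase
from .materials import ElementMaterials
from .meshing import TetMesh
from .volume import LABEL_NAMES

__all__ = ["write_inp", "read_inp", "InpParseError"]

_REGION_BY_NAME = {v.upper(): k for k, v in LABEL_NAMES.items()}
_AMP_NAMES = ("AMP_FX", "AMP_FY", "AMP_FZ")


class InpParseError(ValueError):
    pass


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def _write_id_lines(ids: np.ndarray, per_line: int = 16) -> list[str]:
    out = []
    ids = np.asarray(ids) + 1
    for start in range(0, ids.size, per_line):
        out.append(", ".join(str(i) for i in ids[start : start + per_line]))
    return out


def write_inp(
    mesh: TetMesh,
    materials: ElementMaterials | None = None,
    bc: BoundaryCondition | None = None,
    load: LoadCase | None = None,
) -> str:
    """Serialize mesh (+ optional materials, boundary condition, load case)."""
    lines: list[str] = ["*HEADING", "fractwin plated-tibia model"]

    lines.append("*NODE")
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {_fmt(x)}, {_fmt(y)}, {_fmt(z)}")

    etype = "C3D4" if mesh.order == 1 else "C3D10"
    lines.append(f"*ELEMENT, TYPE={etype}, ELSET=EALL")
    for i, conn in enumerate(mesh.elements, start=1):
        lines.append(f"{i}, " + ", ".join(str(n + 1) for n in conn))

    for label in sorted(set(mesh.region.tolist())):
        name = LABEL_NAMES.get(label, f"LABEL{label}").upper()
        lines.append(f"*ELSET, ELSET=REGION_{name}")
        lines.extend(_write_id_lines(np.flatnonzero(mesh.region == label)))

    for set_name, idx in mesh.node_sets.items():
        lines.append(f"*NSET, NSET={set_name.upper()}")
        lines.extend(_write_id_lines(np.asarray(idx)))

    if materials is not None:
        if materials.n_elements != mesh.n_elements:
            raise ValueError("materials must cover every element")
        pairs = np.column_stack([materials.E, materials.nu])
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        for k, (E, nu) in enumerate(uniq):
            set_name = f"MAT_{k + 1:06d}"
            lines.append(f"*ELSET, ELSET={set_name}")
            lines.extend(_write_id_lines(np.flatnonzero(inverse == k)))
            lines.append(f"*MATERIAL, NAME={set_name}")
            lines.append("*ELASTIC")
            lines.append(f"{_fmt(E)}, {_fmt(nu)}")
            lines.append(f"*SOLID SECTION, ELSET={set_name}, MATERIAL={set_name}")

    if bc is not None:
        lines.append("*BOUNDARY")
        dof_lo, dof_hi = min(bc.dofs) + 1, max(bc.dofs) + 1
        lines.append(f"{bc.node_set.upper()}, {dof_lo}, {dof_hi}")

    if load is not None:
        for c, amp_name in enumerate(_AMP_NAMES):
            lines.append(f"*AMPLITUDE, NAME={amp_name}")
            pairs = []
            for t, v in zip(load.times, load.forces[:, c]):
                pairs.append(f"{_fmt(t)}, {_fmt(v)}")
            for start in range(0, len(pairs), 4):
                lines.append(", ".join(pairs[start : start + 4]))
        n_target = mesh.node_sets.get(load.node_set, np.empty(0)).size
        per_node = 1.0 / n_target if n_target else 1.0
        for c, amp_name in enumerate(_AMP_NAMES):
            lines.append(f"*CLOAD, AMPLITUDE={amp_name}")
            lines.append(f"{load.node_set.upper()}, {c + 1}, {_fmt(per_node)}")

    return "\n".join(lines) + "\n"


def read_inp(text: str):
    """Parse a deck written by :func:`write_inp`.

    Returns ``(mesh, materials, bc, load)``; the last three are ``None``
    when the corresponding sections are absent.
    """
    nodes: list[list[float]] = []
    elements: list[list[int]] = []
    elsets: dict[str, list[int]] = {}
    nsets: dict[str, list[int]] = {}
    mat_props: dict[str, tuple[float, float]] = {}
    amplitudes: dict[str, list[float]] = {}
    cloads: dict[str, tuple[str, int, float]] = {}
    bc_spec: tuple[str, int, int] | None = None

    section = None
    section_arg: dict[str, str] = {}
    pending_material: str | None = None

    def keywords(line: str) -> tuple[str, dict[str, str]]:
        parts = [p.strip() for p in line[1:].split(",")]
        kw = parts[0].upper()
        args = {}
        for p in parts[1:]:
            if "=" in p:
                k, v = p.split("=", 1)
                args[k.strip().upper()] = v.strip()
        return kw, args

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            kw, args = keywords(line)
            if kw in (
                "HEADING", "NODE", "ELEMENT", "ELSET", "NSET", "MATERIAL",
                "ELASTIC", "SOLID SECTION", "BOUNDARY", "AMPLITUDE", "CLOAD",
            ):
                section, section_arg = kw, args
                if kw == "ELSET":
                    elsets.setdefault(args["ELSET"], [])
                elif kw == "NSET":
                    nsets.setdefault(args["NSET"], [])
                elif kw == "MATERIAL":
                    pending_material = args["NAME"]
                elif kw == "AMPLITUDE":
                    amplitudes.setdefault(args["NAME"], [])
            else:
                raise InpParseError(f"line {lineno}: unknown section header {line!r}")
            continue

        try:
            if section == "NODE":
                parts = line.split(",")
                nodes.append([float(p) for p in parts[1:4]])
            elif section == "ELEMENT":
                parts = [int(p) for p in line.split(",")]
                elements.append([p - 1 for p in parts[1:]])
            elif section == "ELSET":
                elsets[section_arg["ELSET"]].extend(int(p) - 1 for p in line.split(",") if p.strip())
            elif section == "NSET":
                nsets[section_arg["NSET"]].extend(int(p) - 1 for p in line.split(",") if p.strip())
            elif section == "ELASTIC":
                if pending_material is None:
                    raise InpParseError(f"line {lineno}: *ELASTIC outside a material block")
                E, nu = (float(p) for p in line.split(",")[:2])
                mat_props[pending_material] = (E, nu)
            elif section == "BOUNDARY":
                parts = [p.strip() for p in line.split(",")]
                bc_spec = (parts[0], int(parts[1]), int(parts[2]))
            elif section == "AMPLITUDE":
                vals = [float(p) for p in line.split(",") if p.strip()]
                amplitudes[section_arg["NAME"]].extend(vals)
            elif section == "CLOAD":
                parts = [p.strip() for p in line.split(",")]
                cloads[section_arg["AMPLITUDE"]] = (parts[0], int(parts[1]) - 1, float(parts[2]))
            elif section in ("HEADING", "MATERIAL", "SOLID SECTION"):
                pass
            else:
                raise InpParseError(f"line {lineno}: data before any section header")
        except InpParseError:
            raise
        except (ValueError, IndexError, KeyError) as exc:
            raise InpParseError(f"line {lineno}: malformed data line {line!r}: {exc}") from exc

    if not nodes or not elements:
        raise InpParseError("deck contains no nodes or no elements")
    nodes_arr = np.asarray(nodes, dtype=float)
    elements_arr = np.asarray(elements, dtype=np.int64)

    region = np.zeros(elements_arr.shape[0], dtype=np.int64)
    for name, ids in elsets.items():
        if name.startswith("REGION_"):
            label_name = name[len("REGION_"):]
            label = _REGION_BY_NAME.get(label_name)
            if label is None:
                try:
                    label = int(label_name.replace("LABEL", ""))
                except ValueError as exc:
                    raise InpParseError(f"unknown region set {name!r}") from exc
            region[np.asarray(ids, dtype=int)] = label

    node_sets = {name.lower(): np.asarray(ids, dtype=np.int64) for name, ids in nsets.items()}
    mesh = TetMesh(nodes_arr, elements_arr, region, node_sets)

    materials = None
    mat_sets = {n: ids for n, ids in elsets.items() if n.startswith("MAT_")}
    if mat_sets:
        E = np.zeros(mesh.n_elements)
        nu = np.zeros(mesh.n_elements)
        for name, ids in mat_sets.items():
            if name not in mat_props:
                raise InpParseError(f"element set {name!r} has no *MATERIAL block")
            idx = np.asarray(ids, dtype=int)
            E[idx], nu[idx] = mat_props[name]
        materials = ElementMaterials(E=E, nu=nu, region=region.copy())

    bc = None
    if bc_spec is not None:
        set_name, lo, hi = bc_spec
        bc = BoundaryCondition(node_set=set_name.lower(), dofs=tuple(range(lo - 1, hi)))

    load = None
    if amplitudes:
        comps = []
        times = None
        for amp_name in _AMP_NAMES:
            flat = np.asarray(amplitudes.get(amp_name, []), dtype=float)
            if flat.size == 0:
                raise InpParseError(f"missing amplitude table {amp_name}")
            t, v = flat[0::2], flat[1::2]
            if times is None:
                times = t
            elif not np.array_equal(times, t):
                raise InpParseError("amplitude tables use inconsistent time grids")
            comps.append(v)
        target = next(iter(cloads.values()))[0].lower() if cloads else "proximal"
        load = LoadCase(times=times, forces=np.column_stack(comps), node_set=target)

    return mesh, materials, bc, load
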