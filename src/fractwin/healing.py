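"""Mechanobiological assessment of the fracture gap and implant.

The mechanical stimulus in each fracture-gap element is summarized by two
rotation-invariant strain measures: the octahedral shear strain

    gamma_oct = (2/3) * sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2)

over the principal strains e_i (distortional stimulus) and the volumetric
strain trace(E) (hydrostatic stimulus, negative in compression). Each
(gamma_oct, eps_vol) pair is classified into a tissue-differentiation
"healing window" — a partition of the stimulus plane into rectangles, in
the spirit of Claes & Heigele-type mechanoregulation theory. The shipped
default window is a configurable surrogate: intramembranous ossification at
low distortion and near-zero volume change, endochondral ossification at
moderate distortion with compression, connective tissue / unfavorable
elsewhere. Its numeric boundaries are scientific inputs, editable via
YAML/JSON, and the partition is verified for completeness on a dense grid
at load time.

Construct stability is judged by the peak implant von Mises stress against
the implant yield strength (default 880 MPa, medical TiAl alloy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fem import FEResult, _check_symmetric
from .meshing import TetMesh

__all__ = [
    "octahedral_shear",
    "volumetric_strain",
    "WindowRule",
    "HealingWindowConfig",
    "default_window",
    "HealingAssessment",
    "assess",
]


def octahedral_shear(E: np.ndarray) -> np.ndarray:
    """Octahedral shear strain of symmetric (..., 3, 3) strain tensors."""
    E = _check_symmetric(E)
    e = np.linalg.eigvalsh(E)
    e1, e2, e3 = e[..., 0], e[..., 1], e[..., 2]
    return (2.0 / 3.0) * np.sqrt((e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2)


def volumetric_strain(E: np.ndarray) -> np.ndarray:
    """Volumetric strain: trace of symmetric (..., 3, 3) strain tensors."""
    E = _check_symmetric(E)
    return np.trace(E, axis1=-2, axis2=-1)


# ---------------------------------------------------------------------------
# Healing window


@dataclass
class WindowRule:
    """One rectangle [g_lo, g_hi) x [v_lo, v_hi) of the stimulus plane.

    Several rules may share a class name; boundaries are lower-inclusive.
    Infinite bounds are allowed.
    """

    name: str
    gamma: tuple[float, float]
    vol: tuple[float, float]
    favorable: bool = False

    def __post_init__(self) -> None:
        if not self.gamma[0] < self.gamma[1] or not self.vol[0] < self.vol[1]:
            raise ValueError(f"rule {self.name!r}: empty interval")
        if self.gamma[0] < 0:
            self.gamma = (0.0, self.gamma[1])

    def contains(self, g: np.ndarray, v: np.ndarray) -> np.ndarray:
        return (
            (g >= self.gamma[0]) & (g < self.gamma[1]) & (v >= self.vol[0]) & (v < self.vol[1])
        )


class HealingWindowConfig:
    """An ordered set of rules partitioning the (gamma_oct >= 0) x eps_vol plane.

    Class indices follow first appearance of each class name in the rule
    list (used for VTK encoding and report ordering). Completeness — every
    stimulus point belongs to exactly one rule — is enforced on a dense grid
    at construction.
    """

    def __init__(self, rules: list[WindowRule], check_grid: int = 200):
        if not rules:
            raise ValueError("healing window needs at least one rule")
        self.rules = list(rules)
        self.class_names: list[str] = []
        for r in self.rules:
            if r.name not in self.class_names:
                self.class_names.append(r.name)
        self.favorable = {
            name: any(r.favorable for r in self.rules if r.name == name)
            for name in self.class_names
        }
        for name in self.class_names:
            flags = {r.favorable for r in self.rules if r.name == name}
            if len(flags) > 1:
                raise ValueError(f"class {name!r} has inconsistent favorable flags")
        self._check_partition(check_grid)

    def _check_partition(self, n: int) -> None:
        g = np.linspace(0.0, 1.0, n)
        v = np.linspace(-0.5, 0.5, n)
        G, V = np.meshgrid(g, v, indexing="ij")
        hits = np.zeros(G.shape, dtype=int)
        for r in self.rules:
            hits += r.contains(G, V).astype(int)
        if hits.min() < 1:
            i, j = np.unravel_index(int(np.argmin(hits)), hits.shape)
            raise ValueError(
                f"healing window incomplete: no class at gamma={G[i, j]:g}, vol={V[i, j]:g}"
            )
        if hits.max() > 1:
            i, j = np.unravel_index(int(np.argmax(hits)), hits.shape)
            raise ValueError(
                f"healing window overlaps: {hits[i, j]} classes at "
                f"gamma={G[i, j]:g}, vol={V[i, j]:g}"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def unfavorable_classes(self) -> list[str]:
        return [c for c in self.class_names if not self.favorable[c]]

    def classify(self, gamma, vol) -> np.ndarray:
        """Class index for each (gamma_oct, eps_vol) pair; -1 never occurs for
        a validated window within the checked domain."""
        g = np.asarray(gamma, dtype=float)
        v = np.asarray(vol, dtype=float)
        out = np.full(np.broadcast(g, v).shape, -1, dtype=int)
        for r in self.rules:
            m = r.contains(g, v) & (out == -1)
            out[m] = self.class_names.index(r.name)
        if np.any(out == -1):
            bad = np.argwhere(out == -1)[0]
            raise ValueError(f"stimulus not covered by the healing window at index {tuple(bad)}")
        return out

    def classify_names(self, gamma, vol):
        idx = self.classify(gamma, vol)
        return np.asarray(self.class_names, dtype=object)[idx]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "classes": [
                {
                    "name": r.name,
                    "gamma": [_num(r.gamma[0]), _num(r.gamma[1])],
                    "vol": [_num(r.vol[0]), _num(r.vol[1])],
                    "favorable": r.favorable,
                }
                for r in self.rules
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HealingWindowConfig":
        rules = [
            WindowRule(
                name=c["name"],
                gamma=(_inf(c["gamma"][0]), _inf(c["gamma"][1])),
                vol=(_inf(c["vol"][0]), _inf(c["vol"][1])),
                favorable=bool(c.get("favorable", False)),
            )
            for c in d["classes"]
        ]
        return cls(rules)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "HealingWindowConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def _num(x: float):
    if np.isinf(x):
        return "inf" if x > 0 else "-inf"
    return float(x)


def _inf(x) -> float:
    if isinstance(x, str):
        return float(x)
    return float(x)


INF = float("inf")


def default_window() -> HealingWindowConfig:
    """The shipped surrogate healing window.

    Intramembranous (direct) bone formation: gamma_oct < 0.05 and |eps_vol|
    < 0.05. Endochondral ossification: 0.05 <= gamma_oct < 0.15 under
    compression (-0.15 <= eps_vol < 0). Everything else — high distortion or
    large volume change — is connective tissue / unfavorable.
    """
    ct = "connective tissue"
    return HealingWindowConfig(
        [
            WindowRule("intramembranous ossification", (0.0, 0.05), (-0.05, 0.05), favorable=True),
            WindowRule("endochondral ossification", (0.05, 0.15), (-0.15, 0.0), favorable=True),
            WindowRule(ct, (0.0, 0.05), (-INF, -0.05)),
            WindowRule(ct, (0.0, 0.05), (0.05, INF)),
            WindowRule(ct, (0.05, 0.15), (-INF, -0.15)),
            WindowRule(ct, (0.05, 0.15), (0.0, INF)),
            WindowRule(ct, (0.15, INF), (-INF, INF)),
        ]
    )


# ---------------------------------------------------------------------------
# Assessment


@dataclass
class HealingAssessment:
    """Cycle-resolved healing-window classification and implant stress check."""

    times: np.ndarray
    class_names: list[str]
    gap_elements: np.ndarray  # element ids in the fracture gap
    gamma_oct: np.ndarray  # (k, n_gap)
    eps_vol: np.ndarray  # (k, n_gap)
    classes: np.ndarray  # (k, n_gap) class indices
    class_fractions: np.ndarray  # (k, n_classes), volume-weighted, rows sum to 1
    unfavorable_fraction: np.ndarray  # (k,)
    worst_unfavorable_fraction: float
    peak_gap_gamma_oct: float
    peak_implant_von_mises: float | None  # MPa; None if no implant elements
    peak_implant_element: int | None
    peak_implant_time_index: int | None
    yield_strength: float
    unfavorable_limit: float
    stable: bool | None  # None = not applicable (no implant)
    healing_ok: bool

    def summary(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "worst_unfavorable_fraction": self.worst_unfavorable_fraction,
            "peak_gap_gamma_oct": self.peak_gap_gamma_oct,
            "peak_implant_von_mises_MPa": self.peak_implant_von_mises,
            "yield_strength_MPa": self.yield_strength,
            "stable": self.stable,
            "healing_ok": self.healing_ok,
            "n_gap_elements": int(self.gap_elements.size),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2, sort_keys=True))

    def fractions_to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.class_fractions, columns=self.class_names)
        df.insert(0, "t_frac", self.times)
        df["unfavorable"] = self.unfavorable_fraction
        df.to_csv(path, index=False)


def assess(
    result: FEResult,
    mesh: TetMesh,
    window: HealingWindowConfig | None = None,
    yield_strength: float = 880.0,
    unfavorable_limit: float = 0.0,
) -> HealingAssessment:
    """Classify every gap element at every sample and check implant stress.

    Class fractions are volume-weighted using the element volumes (IVOL);
    the healing verdict compares the worst-over-time unfavorable fraction
    against ``unfavorable_limit`` (default 0: any gap volume outside the
    window flags the level) and the stability verdict compares the peak
    implant von Mises stress against ``yield_strength``.
    """
    window = window or default_window()
    gap_ids = mesh.gap_elements()
    if gap_ids.size == 0:
        raise ValueError("mesh has no fracture-gap elements to assess")
    impl_ids = mesh.implant_elements()

    k = result.n_samples
    strain = result.strain_history(gap_ids)  # (k, n_gap, 6) engineering Voigt
    from .fem import voigt_to_tensor

    tensors = voigt_to_tensor(strain)
    gamma = octahedral_shear(tensors)
    vol_strain = volumetric_strain(tensors)
    classes = window.classify(gamma, vol_strain)

    weights = result.element_volumes[gap_ids]
    total = weights.sum()
    fractions = np.zeros((k, window.n_classes))
    for c in range(window.n_classes):
        fractions[:, c] = ((classes == c) * weights[None, :]).sum(axis=1) / total
    unfav_idx = [window.class_names.index(c) for c in window.unfavorable_classes()]
    unfav = fractions[:, unfav_idx].sum(axis=1) if unfav_idx else np.zeros(k)

    if impl_ids.size:
        vm = result.von_mises_history(impl_ids)  # (k, n_impl)
        flat = int(np.argmax(vm))
        ti, ei = np.unravel_index(flat, vm.shape)
        peak_vm = float(vm[ti, ei])
        peak_elem = int(impl_ids[ei])
        peak_t = int(ti)
        stable = bool(peak_vm < yield_strength)
    else:
        peak_vm = peak_elem = peak_t = None
        stable = None

    worst_unfav = float(unfav.max())
    return HealingAssessment(
        times=result.times.copy(),
        class_names=list(window.class_names),
        gap_elements=gap_ids,
        gamma_oct=gamma,
        eps_vol=vol_strain,
        classes=classes,
        class_fractions=fractions,
        unfavorable_fraction=unfav,
        worst_unfavorable_fraction=worst_unfav,
        peak_gap_gamma_oct=float(gamma.max()),
        peak_implant_von_mises=peak_vm,
        peak_implant_element=peak_elem,
        peak_implant_time_index=peak_t,
        yield_strength=yield_strength,
        unfavorable_limit=unfavorable_limit,
        stable=stable,
        healing_ok=bool(worst_unfav <= unfavorable_limit),
    )
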