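"""Kinematic rhythms: linear couplings that reduce the tracked DoF.

A rhythm slaves one joint DoF to one or more master DoF through a linear
relation, mirroring the functional units created by ligaments spanning
several joints (e.g. the transverse metatarsal ligaments couple metatarsal
motion). The full 43-dimensional joint vector is recovered from a reduced
vector of independent coordinates by the affine map

    q_full = C @ q_reduced + offset

where every row of ``C`` is either a unit row (an independent DoF) or a
coupling row (a slaved DoF). Solving inverse kinematics directly in the
reduced coordinates makes the rhythms hard constraints by construction.

Six rhythm groups are shipped (all coefficients configurable, default 1.0;
arch interpolation weights default to the ray positions):

1. ``ip`` — distal IP flexion of toes 2-5 follows the proximal IP joint.
2. ``mtp`` — MTP 2-5 flexion follows MTP 1 flexion.
3. ``metatarsal_arch`` — TMT 2-4 flexion interpolates the bounding rays
   TMT 1 / TMT 5 (metatarsal-head height arch).
4. ``tarsal_arch`` — central/lateral cuneonavicular flexion interpolates
   medial cuneonavicular and calcaneocuboid flexion (transverse tarsal arch).
5. ``medial_arch`` — medial cuneonavicular and TMT 1 flexion/adduction are
   slaved to talonavicular flexion/adduction (first-ray longitudinal arch).
6. ``lateral_arch`` — TMT 5 flexion is slaved to calcaneocuboid flexion.

With all six active the reduced dimension is 25 (43 − 18 slaved DoF).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ConstraintConflictError, DimensionError
from .skeleton import KinematicTemplate

__all__ = [
    "RhythmSet",
    "RHYTHM_NAMES",
    "default_coefficients",
    "build_rhythm_set",
    "build_default_rhythms",
    "identity_rhythms",
    "reduced_to_full",
    "rhythm_jacobian",
    "full_to_reduced",
]

Dof = tuple[str, str]  # (child segment, angle name)

RHYTHM_NAMES = (
    "ip",
    "mtp",
    "metatarsal_arch",
    "tarsal_arch",
    "medial_arch",
    "lateral_arch",
)


@dataclass
class RhythmSet:
    """The reduced-to-full affine coordinate map induced by a set of rhythms."""

    coupling_matrix: np.ndarray  # (full_dof, reduced_dof)
    offset: np.ndarray  # (full_dof,)
    reduced_names: list[str]
    independent_indices: np.ndarray  # full-DoF index of each reduced coordinate

    def __post_init__(self) -> None:
        C = np.asarray(self.coupling_matrix, dtype=float)
        self.coupling_matrix = C
        self.offset = np.asarray(self.offset, dtype=float).reshape(C.shape[0])
        self.independent_indices = np.asarray(self.independent_indices, dtype=int)
        if len(self.reduced_names) != C.shape[1]:
            raise DimensionError("reduced_names length != number of columns")
        if np.linalg.matrix_rank(C) != C.shape[1]:
            raise ConstraintConflictError("coupling matrix is rank-deficient")
        # unit rows must select exactly their reduced coordinate
        sel = C[self.independent_indices]
        if not np.array_equal(sel, np.eye(C.shape[1])):
            raise ConstraintConflictError(
                "independent rows of C are not unit selector rows"
            )

    @property
    def full_dim(self) -> int:
        return self.coupling_matrix.shape[0]

    @property
    def reduced_dim(self) -> int:
        return self.coupling_matrix.shape[1]


def reduced_to_full(rhythms: RhythmSet, q_reduced: np.ndarray) -> np.ndarray:
    """Expand reduced coordinates to the full joint vector (exact affine map)."""
    q_reduced = np.atleast_1d(np.asarray(q_reduced, dtype=float))
    if q_reduced.shape[-1] != rhythms.reduced_dim:
        raise DimensionError(
            f"expected {rhythms.reduced_dim} reduced coordinates, "
            f"got {q_reduced.shape[-1]}"
        )
    return q_reduced @ rhythms.coupling_matrix.T + rhythms.offset


def rhythm_jacobian(rhythms: RhythmSet) -> np.ndarray:
    """d q_full / d q_reduced — the constant matrix C."""
    return rhythms.coupling_matrix


def full_to_reduced(rhythms: RhythmSet, q_full: np.ndarray) -> np.ndarray:
    """Extract the independent coordinates from a full joint vector."""
    q_full = np.asarray(q_full, dtype=float)
    if q_full.shape[-1] != rhythms.full_dim:
        raise DimensionError(
            f"expected {rhythms.full_dim} joint angles, got {q_full.shape[-1]}"
        )
    return q_full[..., rhythms.independent_indices]


def build_rhythm_set(
    template: KinematicTemplate,
    slavings: dict[Dof, list[tuple[Dof, float]]],
    offsets: dict[Dof, float] | None = None,
) -> RhythmSet:
    """Build a :class:`RhythmSet` from explicit slave -> [(master, coeff)] relations.

    Masters may themselves be slaved; chains are resolved by substitution.
    A cyclic dependency raises :class:`ConstraintConflictError`.
    """
    offsets = dict(offsets or {})
    for dof in list(slavings) + list(offsets):
        if dof not in template.dof_index:
            raise ConfigurationError(f"unknown DoF {dof!r} in rhythm definition")
    for slave, masters in slavings.items():
        for m, _ in masters:
            if m not in template.dof_index:
                raise ConfigurationError(f"unknown master DoF {m!r}")
            if m == slave:
                raise ConstraintConflictError(f"DoF {slave!r} slaved to itself")

    # Resolve chained masters until every master is an independent DoF.
    resolved: dict[Dof, dict[Dof, float]] = {
        s: {m: c for m, c in ms} for s, ms in slavings.items()
    }
    res_offsets: dict[Dof, float] = {s: offsets.get(s, 0.0) for s in slavings}
    for _ in range(len(slavings) + 1):
        changed = False
        for slave, terms in resolved.items():
            for master in list(terms):
                if master in resolved:
                    coeff = terms.pop(master)
                    if master == slave:
                        raise ConstraintConflictError(
                            f"cyclic rhythm coupling through {slave!r}"
                        )
                    for mm, cc in resolved[master].items():
                        terms[mm] = terms.get(mm, 0.0) + coeff * cc
                    res_offsets[slave] += coeff * res_offsets.get(master, 0.0)
                    changed = True
        if not changed:
            break
    else:
        raise ConstraintConflictError("cyclic rhythm couplings")

    n_full = template.total_dof
    independent = [d for d in template.dof_list if d not in resolved]
    reduced_index = {d: i for i, d in enumerate(independent)}
    C = np.zeros((n_full, len(independent)))
    offset = np.zeros(n_full)
    for dof in template.dof_list:
        row = template.dof_index[dof]
        if dof in resolved:
            for master, coeff in resolved[dof].items():
                C[row, reduced_index[master]] += coeff
            offset[row] = res_offsets[dof]
        else:
            C[row, reduced_index[dof]] = 1.0
    return RhythmSet(
        coupling_matrix=C,
        offset=offset,
        reduced_names=[f"{seg}:{angle}" for seg, angle in independent],
        independent_indices=np.array(
            [template.dof_index[d] for d in independent], dtype=int
        ),
    )


def identity_rhythms(template: KinematicTemplate) -> RhythmSet:
    """The unconstrained model: every joint DoF independent (C = I)."""
    return build_rhythm_set(template, {})


def default_coefficients() -> dict[str, float]:
    """Named coefficients of the default rhythm set (all overridable)."""
    coeffs: dict[str, float] = {}
    for k in range(2, 6):
        coeffs[f"c_ip_{k}"] = 1.0  # DIP_k = c * PIP_k flexion
        coeffs[f"c_mtp_{k}"] = 1.0  # MTP_k = c * MTP_1 flexion
    for k in range(2, 5):  # arch interpolation weight on the medial ray
        coeffs[f"w_mt_{k}"] = (5 - k) / 4.0
    coeffs["w_cn_central"] = 2.0 / 3.0
    coeffs["w_cn_lateral"] = 1.0 / 3.0
    for suffix in ("cn1_flex", "cn1_add", "tmt1_flex", "tmt1_add"):
        coeffs[f"c_mla_{suffix}"] = 1.0  # medial longitudinal arch
    coeffs["c_lla"] = 1.0  # lateral longitudinal arch
    return coeffs


def build_default_rhythms(
    template: KinematicTemplate,
    coefficients: dict[str, float] | None = None,
    enable: dict[str, bool] | None = None,
) -> RhythmSet:
    """The six default rhythm groups as one :class:`RhythmSet`.

    ``coefficients`` overrides entries of :func:`default_coefficients`;
    ``enable`` switches whole rhythm groups on/off (default: all on).
    """
    coeffs = default_coefficients()
    for key, val in (coefficients or {}).items():
        if key not in coeffs:
            raise ConfigurationError(f"unknown rhythm coefficient {key!r}")
        coeffs[key] = float(val)
    enabled = {name: True for name in RHYTHM_NAMES}
    for key, val in (enable or {}).items():
        if key not in enabled:
            raise ConfigurationError(f"unknown rhythm {key!r}")
        enabled[key] = bool(val)

    pf = "plantarflexion"
    add = "adduction"
    slavings: dict[Dof, list[tuple[Dof, float]]] = {}

    if enabled["ip"]:
        for k in range(2, 6):
            slavings[(f"distal_phalanx_{k}", pf)] = [
                ((f"central_phalanx_{k}", pf), coeffs[f"c_ip_{k}"])
            ]
    if enabled["mtp"]:
        for k in range(2, 6):
            slavings[(f"proximal_phalanx_{k}", pf)] = [
                (("proximal_phalanx_1", pf), coeffs[f"c_mtp_{k}"])
            ]
    if enabled["metatarsal_arch"]:
        for k in range(2, 5):
            w = coeffs[f"w_mt_{k}"]
            slavings[(f"metatarsal_{k}", pf)] = [
                (("metatarsal_1", pf), w),
                (("metatarsal_5", pf), 1.0 - w),
            ]
    if enabled["tarsal_arch"]:
        for seg, key in (
            ("central_cuneiform", "w_cn_central"),
            ("lateral_cuneiform", "w_cn_lateral"),
        ):
            w = coeffs[key]
            slavings[(seg, pf)] = [
                (("medial_cuneiform", pf), w),
                (("cuboid", pf), 1.0 - w),
            ]
    if enabled["medial_arch"]:
        slavings[("medial_cuneiform", pf)] = [
            (("navicular", pf), coeffs["c_mla_cn1_flex"])
        ]
        slavings[("medial_cuneiform", add)] = [
            (("navicular", add), coeffs["c_mla_cn1_add"])
        ]
        slavings[("metatarsal_1", pf)] = [
            (("navicular", pf), coeffs["c_mla_tmt1_flex"])
        ]
        slavings[("metatarsal_1", add)] = [
            (("navicular", add), coeffs["c_mla_tmt1_add"])
        ]
    if enabled["lateral_arch"]:
        slavings[("metatarsal_5", pf)] = [(("cuboid", pf), coeffs["c_lla"])]

    return build_rhythm_set(template, slavings)


def rhythms_from_config(
    template: KinematicTemplate, config: dict | None = None
) -> RhythmSet:
    """Build rhythms from a template's rhythm config block.

    ``config`` (or ``template.rhythm_config``) is a dict with optional keys
    ``enable`` (rhythm name -> bool) and ``coefficients`` (name -> float).
    """
    cfg = config if config is not None else (template.rhythm_config or {})
    return build_default_rhythms(
        template,
        coefficients=cfg.get("coefficients"),
        enable=cfg.get("enable"),
    )
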