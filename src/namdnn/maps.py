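"""Prediction-error maps over 2D coordinate scans.

A :class:`GridScan` holds geometries and exact reference samples on a
rectangular grid over two internal coordinates. Error maps report, per
grid node, log10 of the mean absolute component error of a predicted
property (coupled properties scored modulo the optimal phase vector), and
difference maps contrast two models node by node — negative values mean
model A is the more accurate one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .heads import ExcitedStateModel
from .models import DiabaticModel, adiabatize
from .training import best_phase_alignment

__all__ = ["GridScan", "make_grid_scan", "prediction_error_map",
           "error_difference_map", "ERROR_FLOOR"]

ERROR_FLOOR = 1e-12   # before log10, keeps perfect nodes finite


@dataclass
class GridScan:
    axis_names: tuple            # two coordinate names
    axis_values: tuple           # (array [n1], array [n2])
    geometries: list             # n1*n2, row-major
    references: list             # matching MultiStateSample objects

    def __post_init__(self):
        n1, n2 = (len(self.axis_values[0]), len(self.axis_values[1]))
        if len(self.geometries) != n1 * n2 or len(self.references) != n1 * n2:
            raise ValueError("grid is not rectangular and complete")

    @property
    def shape(self) -> tuple:
        return (len(self.axis_values[0]), len(self.axis_values[1]))


def make_grid_scan(model: DiabaticModel, n1: int = 21, n2: int = 21,
                   axes=(0, 1), ranges: Optional[list] = None,
                   fixed: Optional[np.ndarray] = None) -> GridScan:
    """Rectangular scan over two internal coordinates of a diabatic model;
    the remaining coordinates are held at ``fixed`` (default 0)."""
    ranges = ranges or [model.internal_ranges[axes[0]],
                        model.internal_ranges[axes[1]]]
    a1 = np.linspace(*ranges[0], n1)
    a2 = np.linspace(*ranges[1], n2)
    base = np.zeros(len(model.internal_ranges)) if fixed is None \
        else np.asarray(fixed, dtype=float)
    geometries, references = [], []
    for x1 in a1:
        for x2 in a2:
            q = base.copy()
            q[axes[0]], q[axes[1]] = x1, x2
            geo = model.geometry(q)
            geometries.append(geo)
            references.append(adiabatize(model, geo))
    names = (f"q{axes[0]}", f"q{axes[1]}")
    return GridScan(names, (a1, a2), geometries, references)


_COUPLED = ("smooth_nacs", "transition_dipoles")


def prediction_error_map(model: ExcitedStateModel, grid: GridScan,
                         prop: str = "smooth_nacs",
                         pair: Optional[int] = None) -> np.ndarray:
    """log10 mean absolute component error of ``prop`` per grid node.

    Coupled properties are compared modulo the best phase vector per node;
    ``pair`` restricts the score to one state pair (flat pair index).
    """
    space = model.state_space
    need = {"energies": ("energies",), "forces": ("forces",),
            "smooth_nacs": ("nacs",), "nacs": ("nacs",),
            "transition_dipoles": ("dipoles",),
            "permanent_dipoles": ("dipoles",)}[prop]
    preds = model.predict(grid.geometries, need)
    values = np.empty(len(grid.geometries))
    for k, (pr, ref) in enumerate(zip(preds, grid.references)):
        a = getattr(pr, prop)
        b = getattr(ref, prop)
        if prop in _COUPLED:
            signs = best_phase_alignment({prop: a}, {prop: b}, space)
            b = b * signs.reshape((-1,) + (1,) * (b.ndim - 1))
        if pair is not None and prop in ("smooth_nacs", "nacs",
                                         "transition_dipoles"):
            a, b = a[pair], b[pair]
        values[k] = np.mean(np.abs(a - b))
    values = np.maximum(values, ERROR_FLOOR)
    return np.log10(values).reshape(grid.shape)


def error_difference_map(map_a: np.ndarray, map_b: np.ndarray) -> np.ndarray:
    """Elementwise difference of two error maps on identical grids;
    antisymmetric under swapping the arguments."""
    map_a, map_b = np.asarray(map_a), np.asarray(map_b)
    if map_a.shape != map_b.shape:
        raise ValueError(
            f"grid shapes differ: {map_a.shape} vs {map_b.shape}")
    return map_a - map_b
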