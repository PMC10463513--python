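"""Declarative vegetation-index panel.

Indices are scalar combinations of the five mean plot digital numbers
(B, G, R, RE, NIR). The default registry holds 31 widely used indices —
including TGI, GCI, CIVE and GNDVI in their canonical forms — loaded from
a YAML data file, so the panel can be swapped without code changes.

Formulas are written in a minimal arithmetic grammar (``+ - * / ^``,
parentheses, band symbols, numeric constants) and evaluated safely via the
Python ``ast`` module restricted to those node types. A zero denominator
(or any non-finite result) yields NaN, the package-wide flag for a missing
predictor value.
"""

from __future__ import annotations

import ast
import operator
from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .traits import BANDS

_BINOPS = {
    ast.Add: operator.add,
    ast.Sub: operator.sub,
    ast.Mult: operator.mul,
    ast.Div: operator.truediv,
    ast.Pow: operator.pow,
}
_UNARYOPS = {ast.UAdd: operator.pos, ast.USub: operator.neg}


@dataclass(frozen=True)
class IndexDefinition:
    name: str
    formula: str
    scale_invariant: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        # parse once at construction so bad formulas fail loudly and early
        object.__setattr__(self, "_tree", _parse(self.formula))

    def __call__(self, dns: Mapping[str, float]) -> float:
        with np.errstate(divide="ignore", invalid="ignore"):
            try:
                value = _eval(self._tree, dns)  # type: ignore[attr-defined]
            except ZeroDivisionError:
                return float("nan")
        return float(value) if np.isfinite(value) else float("nan")


def _parse(formula: str) -> ast.expr:
    tree = ast.parse(formula.replace("^", "**"), mode="eval").body
    _validate(tree)
    return tree


def _validate(node: ast.expr) -> None:
    if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
        _validate(node.left)
        _validate(node.right)
    elif isinstance(node, ast.UnaryOp) and type(node.op) in _UNARYOPS:
        _validate(node.operand)
    elif isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        pass
    elif isinstance(node, ast.Name):
        if node.id not in BANDS:
            raise ValueError(f"unknown symbol {node.id!r}; allowed: {BANDS}")
    else:
        raise ValueError(f"disallowed expression element: {ast.dump(node)}")


def _eval(node: ast.expr, env: Mapping[str, float]) -> float:
    if isinstance(node, ast.BinOp):
        return _BINOPS[type(node.op)](_eval(node.left, env), _eval(node.right, env))
    if isinstance(node, ast.UnaryOp):
        return _UNARYOPS[type(node.op)](_eval(node.operand, env))
    if isinstance(node, ast.Constant):
        return float(node.value)
    return float(env[node.id])  # ast.Name, validated at parse time


class IndexRegistry:
    """Ordered collection of index definitions; order is registration
    order and determines column order in every emitted table."""

    def __init__(self, definitions: Iterable[IndexDefinition] = ()) -> None:
        self._defs: dict[str, IndexDefinition] = {}
        for d in definitions:
            self.add(d)

    def add(self, defn: IndexDefinition) -> None:
        if defn.name in self._defs:
            raise ValueError(f"duplicate index name {defn.name!r}")
        self._defs[defn.name] = defn

    def __len__(self) -> int:
        return len(self._defs)

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def __getitem__(self, name: str) -> IndexDefinition:
        try:
            return self._defs[name]
        except KeyError:
            raise KeyError(f"index {name!r} not in registry") from None

    def __iter__(self):
        return iter(self._defs.values())

    @property
    def names(self) -> list[str]:
        return list(self._defs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "IndexRegistry":
        entries = yaml.safe_load(Path(path).read_text())
        return cls(
            IndexDefinition(
                name=e["name"],
                formula=e["formula"],
                scale_invariant=bool(e.get("scale_invariant", False)),
                description=e.get("description", ""),
            )
            for e in entries
        )


def default_registry() -> IndexRegistry:
    """The packaged 31-index panel."""
    return IndexRegistry.from_yaml(str(files("uavbiomass.data") / "indices.yaml"))


def _as_env(dns: Mapping[str, float] | Sequence[float]) -> dict[str, float]:
    if isinstance(dns, Mapping):
        return {b: float(dns[b]) for b in BANDS}
    dns = np.asarray(dns, dtype=float)
    if dns.shape != (len(BANDS),):
        raise ValueError("dns must be a 5-vector in band order (B,G,R,RE,NIR)")
    return dict(zip(BANDS, dns))


def compute_index(defn: IndexDefinition | str, dns, registry: IndexRegistry | None = None) -> float:
    """Evaluate one index on a 5-vector (or band-keyed mapping) of DNs."""
    if isinstance(defn, str):
        registry = default_registry() if registry is None else registry
        defn = registry[defn]
    return defn(_as_env(dns))


def compute_panel(dns, registry: IndexRegistry | None = None) -> dict[str, float]:
    """Evaluate every registered index; missing values surface as NaN."""
    registry = default_registry() if registry is None else registry
    if len(registry) == 0:
        raise ValueError("registry holds no index definitions")
    env = _as_env(dns)
    return {d.name: d(env) for d in registry}


def list_indices(registry: IndexRegistry | None = None) -> list[str]:
    return (default_registry() if registry is None else registry).names


def attach_panel(table: pd.DataFrame, registry: IndexRegistry | None = None) -> pd.DataFrame:
    """Append one VI column per registry entry to a plot table carrying
    mean-DN columns ``dn_B .. dn_NIR``. Rows with missing DNs get NaN."""
    registry = default_registry() if registry is None else registry
    dn_cols = [f"dn_{b}" for b in BANDS]
    missing = [c for c in dn_cols if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks mean-DN columns: {missing}")
    out = table.copy()
    values = {name: np.full(len(table), np.nan) for name in registry.names}
    dn = table[dn_cols].to_numpy(dtype=float)
    for i in range(len(table)):
        if not np.all(np.isfinite(dn[i])):
            continue
        env = dict(zip(BANDS, dn[i]))
        for d in registry:
            values[d.name][i] = d(env)
    for name, col in values.items():
        out[name] = col
    return out
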