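"""Readers and writers for round-robin data, norm parameters and reports.

Round-robin input comes either as a long CSV (``actor,partner,value``,
12 rows) or as a 4x4 matrix CSV with role labels as header and row names
and empty diagonal cells.  Norm parameters come as JSON or YAML with the
schema documented in :func:`read_norms`.  Decimal parsing is
locale-independent (dot separator only); pair keys use ASCII arrows
(``A->B`` for directed, ``A<->B`` for unordered).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any, Mapping, Tuple

import pandas as pd
import yaml

from .assessment import AssessmentReport
from .norms import SRMPopulationParameters
from .roundrobin import RoleSet, RoundRobinData, ValidationError

__all__ = [
    "read_dyads",
    "read_dyads_long",
    "read_dyads_matrix",
    "write_dyads_long",
    "write_dyads_matrix",
    "read_norms",
    "write_norms",
    "write_report",
]

_LONG_COLUMNS = ["actor", "partner", "value"]


def read_dyads(path: str | Path) -> RoundRobinData:
    """Read a round robin from CSV, auto-detecting long or matrix form.

    A file whose header starts with ``actor,partner,value`` is parsed as
    long form; anything else is treated as a 4x4 matrix with labelled
    rows and columns.  Role order is taken from the file.
    """
    path = Path(path)
    header = pd.read_csv(path, nrows=0)
    cols = [str(c).strip().lower() for c in header.columns]
    if cols[: len(_LONG_COLUMNS)] == _LONG_COLUMNS:
        return read_dyads_long(path)
    return read_dyads_matrix(path)


def read_dyads_long(path: str | Path) -> RoundRobinData:
    """Parse the long form: header ``actor,partner,value``, 12 data rows."""
    df = pd.read_csv(path, dtype={0: str, 1: str})
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing_cols = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing columns {missing_cols}")

    values: dict[Tuple[str, str], float] = {}
    roles_in_order: list[str] = []
    for idx, row in df.iterrows():
        a, p = str(row["actor"]).strip(), str(row["partner"]).strip()
        try:
            v = float(row["value"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: row {idx + 2}: non-numeric value {row['value']!r} "
                f"for pair ({a}, {p})"
            ) from None
        if math.isnan(v):
            raise ValidationError(f"{path}: row {idx + 2}: missing value for pair ({a}, {p})")
        if a == p:
            raise ValidationError(f"{path}: row {idx + 2}: self-pair ({a}, {a})")
        if (a, p) in values:
            raise ValidationError(f"{path}: row {idx + 2}: duplicate pair ({a}, {p})")
        values[(a, p)] = v
        for r in (a, p):
            if r not in roles_in_order:
                roles_in_order.append(r)

    if len(roles_in_order) != 4:
        raise ValidationError(
            f"{path}: expected exactly 4 roles, found {len(roles_in_order)}: "
            f"{roles_in_order}"
        )
    roles = RoleSet(tuple(roles_in_order))
    missing = [d for d in roles.dyads if d not in values]
    if missing:
        raise ValidationError(f"{path}: missing rows for pairs {missing}")
    return RoundRobinData(roles, values)


def read_dyads_matrix(path: str | Path) -> RoundRobinData:
    """Parse the matrix form: 4x4 with role labels, empty diagonal."""
    df = pd.read_csv(path, index_col=0)
    col_roles = [str(c).strip() for c in df.columns]
    row_roles = [str(r).strip() for r in df.index]
    if len(col_roles) != 4 or row_roles != col_roles:
        raise ValidationError(
            f"{path}: matrix form requires identical 4-role row and column "
            f"labels, got rows {row_roles} and columns {col_roles}"
        )
    roles = RoleSet(tuple(col_roles))
    values: dict[Tuple[str, str], float] = {}
    for a in row_roles:
        for p in col_roles:
            cell = df.loc[a, p]
            if a == p:
                if not (pd.isna(cell) or str(cell).strip() == ""):
                    raise ValidationError(
                        f"{path}: diagonal cell ({a}, {a}) must be empty, got {cell!r}"
                    )
                continue
            try:
                v = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: non-numeric value {cell!r} in cell ({a}, {p})"
                ) from None
            if math.isnan(v):
                raise ValidationError(f"{path}: empty off-diagonal cell ({a}, {p})")
            values[(a, p)] = v
    return RoundRobinData(roles, values)


def write_dyads_long(data: RoundRobinData, path: str | Path) -> None:
    dyads = data.roles.dyads
    pd.DataFrame(
        {
            "actor": [a for a, _ in dyads],
            "partner": [p for _, p in dyads],
            "value": [data.values[d] for d in dyads],
        }
    ).to_csv(path, index=False)


def write_dyads_matrix(data: RoundRobinData, path: str | Path) -> None:
    labels = list(data.roles.labels)
    df = pd.DataFrame(data.matrix(), index=labels, columns=labels)
    df.to_csv(path)


def _pair_key(a: str, p: str) -> str:
    return f"{a}->{p}"


def _parse_pair(key: str, sep: str, where: str) -> Tuple[str, str]:
    parts = [s.strip() for s in key.split(sep)]
    if len(parts) != 2 or not all(parts):
        raise ValidationError(f"{where}: malformed pair key {key!r} (expected 'A{sep}B')")
    return parts[0], parts[1]


def read_norms(path: str | Path) -> SRMPopulationParameters:
    """Read norm parameters from JSON (``.json``) or YAML (``.yaml``/``.yml``).

    Expected top-level keys: ``roles`` (list of 4), ``family``
    (``{mean, var}``), ``actor`` and ``partner`` (role -> ``{mean, var}``),
    ``relationship`` (``"A->B"`` -> ``{mean, var}``),
    ``generalized_reciprocity`` (role -> value), ``dyadic_reciprocity``
    (``"A<->B"`` -> value) and ``reciprocity_scale`` (``correlation`` or
    ``covariance``).  Optional: ``variance_significant`` (effect id ->
    bool).  Validation failures name the offending key path.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")

    def _require(key: str) -> Any:
        if key not in raw:
            raise ValidationError(f"{path}: missing required key '{key}'")
        return raw[key]

    def _mean_var(obj: Any, where: str) -> Tuple[float, float]:
        if not isinstance(obj, Mapping) or "mean" not in obj or "var" not in obj:
            raise ValidationError(f"{path}: '{where}' must be a mapping with 'mean' and 'var'")
        try:
            return float(obj["mean"]), float(obj["var"])
        except (TypeError, ValueError):
            raise ValidationError(f"{path}: non-numeric mean/var at '{where}'") from None

    roles = RoleSet(tuple(str(r) for r in _require("roles")))
    fam_mean, fam_var = _mean_var(_require("family"), "family")

    def _role_block(key: str) -> tuple[dict[str, float], dict[str, float]]:
        block = _require(key)
        means, vars_ = {}, {}
        for r in roles.labels:
            if r not in block:
                raise ValidationError(f"{path}: '{key}' is missing role '{r}'")
            means[r], vars_[r] = _mean_var(block[r], f"{key}.{r}")
        return means, vars_

    actor_mean, actor_var = _role_block("actor")
    partner_mean, partner_var = _role_block("partner")

    rel_block = _require("relationship")
    rel_mean: dict[Tuple[str, str], float] = {}
    rel_var: dict[Tuple[str, str], float] = {}
    for key, obj in rel_block.items():
        pair = _parse_pair(str(key), "->", f"{path}: relationship")
        rel_mean[pair], rel_var[pair] = _mean_var(obj, f"relationship.{key}")

    gen_block = _require("generalized_reciprocity")
    gen = {}
    for r in roles.labels:
        if r not in gen_block:
            raise ValidationError(f"{path}: 'generalized_reciprocity' is missing role '{r}'")
        gen[r] = float(gen_block[r])

    dyad_block = _require("dyadic_reciprocity")
    dyad = {}
    for key, v in dyad_block.items():
        a, b = _parse_pair(str(key), "<->", f"{path}: dyadic_reciprocity")
        dyad[roles.sort_pair(a, b)] = float(v)

    scale = str(_require("reciprocity_scale"))
    sig_raw = raw.get("variance_significant")
    sig = {str(k): bool(v) for k, v in sig_raw.items()} if sig_raw else None

    return SRMPopulationParameters(
        roles=roles,
        family_mean=fam_mean,
        family_var=fam_var,
        actor_mean=actor_mean,
        actor_var=actor_var,
        partner_mean=partner_mean,
        partner_var=partner_var,
        rel_mean=rel_mean,
        rel_var=rel_var,
        generalized_reciprocity=gen,
        dyadic_reciprocity=dyad,
        reciprocity_scale=scale,
        variance_significant=sig,
    )


def write_norms(params: SRMPopulationParameters, path: str | Path) -> None:
    """Serialize norm parameters to JSON or YAML (by file suffix)."""
    roles = params.roles
    doc: dict[str, Any] = {
        "roles": list(roles.labels),
        "family": {"mean": params.family_mean, "var": params.family_var},
        "actor": {
            r: {"mean": params.actor_mean[r], "var": params.actor_var[r]}
            for r in roles.labels
        },
        "partner": {
            r: {"mean": params.partner_mean[r], "var": params.partner_var[r]}
            for r in roles.labels
        },
        "relationship": {
            _pair_key(a, p): {"mean": params.rel_mean[(a, p)], "var": params.rel_var[(a, p)]}
            for a, p in roles.dyads
        },
        "generalized_reciprocity": {
            r: params.generalized_reciprocity[r] for r in roles.labels
        },
        "dyadic_reciprocity": {
            f"{a}<->{b}": params.dyadic_reciprocity[(a, b)]
            for a, b in roles.unordered_dyads
        },
        "reciprocity_scale": params.reciprocity_scale,
    }
    if params.variance_significant is not None:
        doc["variance_significant"] = dict(params.variance_significant)
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2) + "\n")


def write_report(
    report: AssessmentReport,
    path: str | Path,
    fmt: str = "csv",
    digits: int = 3,
) -> None:
    """Write an assessment report as CSV (rounded) or JSON (full precision)."""
    path = Path(path)
    if fmt == "csv":
        report.to_dataframe(digits=digits).to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(report.to_dict(), indent=2) + "\n")
    else:
        raise ValidationError(f"unknown report format {fmt!r} (use 'csv' or 'json')")
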