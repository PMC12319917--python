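"""Star-schema property store: metadata-described results for configurations.

Result *kinds* live as rows in a ``property`` dimension table and the values
themselves in a dense ``data`` fact table, so a new property type is a row
insert — no schema migration, definable while the store is open and in use.
Vector values are stored as ordered child rows keyed by index, keeping the
fact table scalar and SQL-queryable.  Uncertainties are companion properties
named ``"<name>,stderr"``.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

import pandas as pd

from .errors import StoreError, ValidationError

VALUE_KINDS = ("integer", "real", "text", "vector-of-real")

#: properties every store pre-registers
STANDARD_PROPERTIES = (
    ("electronic energy", "real", "kcal/mol", "total electronic energy"),
    ("enthalpy of formation", "real", "kcal/mol", "standard enthalpy of formation"),
    ("dipole moment", "real", "debye", "magnitude of the molecular dipole"),
    ("volume", "real", "angstrom^3", "cell or molecular volume"),
    ("band gap", "real", "eV", "electronic band gap"),
    ("density", "real", "g/ml", "mass density"),
)


@dataclass(frozen=True)
class PropertyDefinition:
    name: str
    value_kind: str
    units: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}"
            )


@dataclass(frozen=True)
class PropertyRecord:
    configuration: Any
    property: str
    value: Any
    provenance: str | None = None


_SCHEMA = """
CREATE TABLE IF NOT EXISTS property (
    id INTEGER PRIMARY KEY, name TEXT UNIQUE NOT NULL, value_kind TEXT NOT NULL,
    units TEXT, description TEXT);
CREATE TABLE IF NOT EXISTS data (
    id INTEGER PRIMARY KEY, configuration TEXT NOT NULL,
    property INTEGER NOT NULL REFERENCES property(id),
    idx INTEGER NOT NULL DEFAULT 0,
    int_value INTEGER, real_value REAL, text_value TEXT, provenance TEXT);
"""


class PropertyStore:
    """Property definitions plus records, backed by an embedded relational file.

    The store may live in the same sqlite file as the structural data model;
    its two tables are created on demand and never touch the structural ones.
    """

    def __init__(self, path=None):
        self.path = Path(path) if path is not None else None
        target = str(self.path) if self.path is not None else ":memory:"
        try:
            self._conn = sqlite3.connect(target)
            self._conn.executescript(_SCHEMA)
        except sqlite3.DatabaseError as exc:
            raise StoreError(f"cannot open property store {target}: {exc}") from exc
        for name, kind, units, desc in STANDARD_PROPERTIES:
            self.define(PropertyDefinition(name, kind, units, desc))
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()

    # -- definitions --------------------------------------------------------
    def define(self, defn: PropertyDefinition) -> str:
        """Register a property; identical redefinition is a no-op."""
        row = self._conn.execute(
            "SELECT value_kind, units FROM property WHERE name=?", (defn.name,)
        ).fetchone()
        if row is not None:
            if (row[0], row[1]) != (defn.value_kind, defn.units):
                raise ValidationError(
                    f"property {defn.name!r} already defined as kind={row[0]!r} "
                    f"units={row[1]!r}; conflicting redefinition kind="
                    f"{defn.value_kind!r} units={defn.units!r}"
                )
            return defn.name
        self._conn.execute(
            "INSERT INTO property (name, value_kind, units, description) VALUES (?,?,?,?)",
            (defn.name, defn.value_kind, defn.units, defn.description),
        )
        self._conn.commit()
        return defn.name

    def definition(self, name: str) -> PropertyDefinition:
        row = self._conn.execute(
            "SELECT name, value_kind, units, description FROM property WHERE name=?",
            (name,),
        ).fetchone()
        if row is None:
            raise KeyError(name)
        return PropertyDefinition(*row)

    def defined(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT name FROM property ORDER BY id")]

    # -- records ------------------------------------------------------------
    def store(self, configuration, name: str, value, provenance: str | None = None) -> None:
        """Store one value; the property must already be defined."""
        row = self._conn.execute(
            "SELECT id, value_kind FROM property WHERE name=?", (name,)
        ).fetchone()
        if row is None:
            raise ValidationError(
                f"property {name!r} is not defined; call define() first"
            )
        prop_id, kind = row
        cfg = str(configuration)
        cols = dict(int_value=None, real_value=None, text_value=None)
        if kind == "integer":
            cols["int_value"] = int(value)
            rows = [(cfg, prop_id, 0, cols["int_value"], None, None, provenance)]
        elif kind == "real":
            cols["real_value"] = float(value)
            rows = [(cfg, prop_id, 0, None, cols["real_value"], None, provenance)]
        elif kind == "text":
            rows = [(cfg, prop_id, 0, None, None, str(value), provenance)]
        else:  # vector-of-real
            rows = [(cfg, prop_id, i, None, float(v), None, provenance)
                    for i, v in enumerate(value)]
        self._conn.executemany(
            "INSERT INTO data (configuration, property, idx, int_value, real_value,"
            " text_value, provenance) VALUES (?,?,?,?,?,?,?)", rows,
        )
        self._conn.commit()

    def query(
        self,
        name: str | None = None,
        configuration=None,
        value_min: float | None = None,
        value_max: float | None = None,
    ) -> list[PropertyRecord]:
        """Records satisfying all given filters; empty result is not an error."""
        sql = ("SELECT d.configuration, p.name, p.value_kind, d.idx, d.int_value,"
               " d.real_value, d.text_value, d.provenance FROM data d"
               " JOIN property p ON p.id=d.property WHERE 1=1")
        args: list = []
        if name is not None:
            sql += " AND p.name=?"
            args.append(name)
        if configuration is not None:
            sql += " AND d.configuration=?"
            args.append(str(configuration))
        sql += " ORDER BY d.id"
        out: list[PropertyRecord] = []
        vectors: dict[tuple, list] = {}
        for (cfg, pname, kind, idx, iv, rv, tv, prov) in self._conn.execute(sql, args):
            if kind == "vector-of-real":
                vectors.setdefault((cfg, pname, prov), []).append((idx, rv))
                continue
            value = iv if kind == "integer" else rv if kind == "real" else tv
            out.append(PropertyRecord(cfg, pname, value, prov))
        for (cfg, pname, prov), items in vectors.items():
            vec = [v for _, v in sorted(items)]
            out.append(PropertyRecord(cfg, pname, vec, prov))
        if value_min is not None:
            out = [r for r in out if _scalar(r.value) is not None
                   and _scalar(r.value) >= value_min]
        if value_max is not None:
            out = [r for r in out if _scalar(r.value) is not None
                   and _scalar(r.value) <= value_max]
        return out

    def n_data_rows(self) -> int:
        return self._conn.execute("SELECT COUNT(*) FROM data").fetchone()[0]

    def dump(self) -> list[tuple]:
        """Canonical row dump, used to compare stores for identity."""
        return list(self._conn.execute(
            "SELECT d.configuration, p.name, d.idx, d.int_value, d.real_value,"
            " d.text_value, d.provenance FROM data d JOIN property p"
            " ON p.id=d.property ORDER BY d.id"))

    def to_csv(self, path, **query_kwargs) -> None:
        """Export query results as CSV."""
        records = self.query(**query_kwargs)
        frame = pd.DataFrame(
            [(r.configuration, r.property, r.value if not isinstance(r.value, list)
              else ";".join(map(str, r.value)), r.provenance) for r in records],
            columns=["configuration", "property", "value", "provenance"],
        )
        frame.to_csv(path, index=False)


def _scalar(value) -> Optional[float]:
    if isinstance(value, (int, float)):
        return float(value)
    return None
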