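"""Electronic descriptors for aryl bromide substrates.

Each mono-substituted aryl bromide is encoded as a 2-element Hammett vector
(sigma_meta, sigma_para): the position carrying the substituent holds its
tabulated sigma constant, the unsubstituted position holds 0 (the sigma of
hydrogen).  Ortho substitution is rejected rather than approximated — sigma
constants do not capture the steric component ortho groups introduce.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple

import pandas as pd

from .errors import UnknownSubstituentError, UnsupportedPositionError

POSITIONS = ("meta", "para")


class HammettVector(NamedTuple):
    sigma_meta: float
    sigma_para: float

    @property
    def sigma_eff(self) -> float:
        """Sum of the two components; equals the single active sigma for a
        mono-substituted substrate."""
        return self.sigma_meta + self.sigma_para


@dataclass(frozen=True)
class HammettTable:
    """Lookup of substituent symbol -> (sigma_meta, sigma_para)."""

    values: Mapping[str, tuple[float, float]]

    def __post_init__(self):
        for sym, (sm, sp) in self.values.items():
            if not (pd.notna(sm) and pd.notna(sp)):
                raise ValueError(f"non-finite sigma for substituent {sym!r}")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.values

    def symbols(self) -> list[str]:
        return sorted(self.values)

    def lookup(self, symbol: str) -> tuple[float, float]:
        try:
            return self.values[symbol]
        except KeyError:
            raise UnknownSubstituentError(
                f"substituent {symbol!r} not in Hammett table; "
                f"available: {', '.join(self.symbols())}"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s, sm, sp) for s, (sm, sp) in self.values.items()],
            columns=["substituent", "sigma_meta", "sigma_para"],
        )


def load_hammett_table(path: str | Path | None = None) -> HammettTable:
    """Load a sigma table from CSV (``substituent, sigma_meta, sigma_para``).

    With no path, the bundled Hansch-Leo-Taft values are used.
    """
    if path is None:
        from importlib.resources import files

        path = files("kinetree.data") / "hammett_sigma.csv"
    df = pd.read_csv(path, comment="#")
    required = {"substituent", "sigma_meta", "sigma_para"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Hammett table missing columns: {sorted(missing)}")
    values = {
        str(row.substituent): (float(row.sigma_meta), float(row.sigma_para))
        for row in df.itertuples()
    }
    if "H" in values and values["H"] != (0.0, 0.0):
        raise ValueError("hydrogen must map to (0, 0)")
    return HammettTable(values=values)


def save_hammett_table(table: HammettTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def encode_substrate(
    substituent: str, position: str, table: HammettTable
) -> HammettVector:
    """Encode one aryl bromide as its (sigma_meta, sigma_para) vector.

    Examples: ("CN", "meta") -> (sigma_m(CN), 0); ("H", anything) -> (0, 0).
    """
    if position not in POSITIONS:
        raise UnsupportedPositionError(
            f"position {position!r} unsupported; only meta/para substitution "
            "is modelled (ortho introduces steric effects sigma ignores)"
        )
    sm, sp = table.lookup(substituent)
    if position == "meta":
        return HammettVector(sigma_meta=sm, sigma_para=0.0)
    return HammettVector(sigma_meta=0.0, sigma_para=sp)
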