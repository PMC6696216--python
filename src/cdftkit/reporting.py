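"""Rounded descriptor reports with stable, machine-consumable columns.

Rounding convention: banker's rounding (half-to-even) on the shortest
decimal representation of the full-precision value, applied only at report
time. The reported net electrophilicity is the sum of the *reported*
(rounded) electrodonating and electroaccepting powers, so the printed
columns stay internally consistent; the stored full-precision value is
always ω− + ω+.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from . import __version__
from .constants import (
    DESCRIPTOR_DECIMALS,
    HARTREE_TO_EV,
    HC_EV_NM,
    PKA_DECIMALS,
    PKA_INTERCEPT,
    PKA_SLOPE,
)
from .errors import CdftError
from .global_reactivity import describe
from .models import (
    CondensedSiteTable,
    DescriptorReport,
    FrontierOrbitalRecord,
    GlobalDescriptorSet,
    PkaModel,
)

#: Column order of the global report (descriptor block mirrors the
#: published table layout).
GLOBAL_COLUMNS = [
    "molecule",
    "epsilon_homo",
    "epsilon_lumo",
    "gap",
    "lambda_max_nm",
    "electronegativity",
    "global_hardness",
    "electrophilicity",
    "electrodonating_power",
    "electroaccepting_power",
    "net_electrophilicity",
    "pka",
]

SITE_REPORT_COLUMNS = [
    "atom_index",
    "element",
    "f_plus",
    "f_minus",
    "dual_scaled",
    "parr_plus",
    "parr_minus",
]


@dataclass(frozen=True)
class ToolkitConfig:
    """Constants applied by a reporting run; every field is overridable."""

    pka_intercept: float = PKA_INTERCEPT
    pka_slope: float = PKA_SLOPE
    hc_ev_nm: float = HC_EV_NM
    hartree_to_ev: float = HARTREE_TO_EV
    descriptor_decimals: int = DESCRIPTOR_DECIMALS
    pka_decimals: int = PKA_DECIMALS

    @property
    def pka_model(self) -> PkaModel:
        return PkaModel(intercept=self.pka_intercept, slope=self.pka_slope)

    def with_overrides(self, **overrides) -> "ToolkitConfig":
        clean = {k: v for k, v in overrides.items() if v is not None}
        return replace(self, **clean)

    def as_metadata(self) -> dict:
        return {
            "toolkit_version": __version__,
            "pka_intercept": self.pka_intercept,
            "pka_slope": self.pka_slope,
            "hc_ev_nm": self.hc_ev_nm,
            "hartree_to_ev": self.hartree_to_ev,
            "descriptor_decimals": self.descriptor_decimals,
            "pka_decimals": self.pka_decimals,
        }


def round_reported(value: float, decimals: int) -> float:
    """Round half-to-even at a decimal precision, on the shortest decimal
    representation of the float (so 3.4545 stored as a float rounds on
    '3.4545', not on its binary expansion)."""
    q = Decimal(1).scaleb(-decimals) if decimals > 0 else Decimal(1)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))


def report_global_row(ds: GlobalDescriptorSet, config: Optional[ToolkitConfig] = None) -> dict:
    """One rounded report row from a full-precision descriptor set."""
    cfg = config or ToolkitConfig()
    nd = cfg.descriptor_decimals
    w_minus = round_reported(ds.electrodonating_power, nd)
    w_plus = round_reported(ds.electroaccepting_power, nd)
    row = {
        "molecule": ds.label,
        "gap": round_reported(ds.global_hardness, nd),
        "lambda_max_nm": None
        if ds.lambda_max_nm is None
        else int(round_reported(ds.lambda_max_nm, 0)),
        "electronegativity": round_reported(ds.electronegativity, nd),
        "global_hardness": round_reported(ds.global_hardness, nd),
        "electrophilicity": round_reported(ds.electrophilicity, nd),
        "electrodonating_power": w_minus,
        "electroaccepting_power": w_plus,
        "net_electrophilicity": round_reported(w_minus + w_plus, nd),
        "pka": None if ds.pka is None else round_reported(ds.pka, cfg.pka_decimals),
    }
    return row


def global_report(
    records: Iterable[FrontierOrbitalRecord], config: Optional[ToolkitConfig] = None
) -> DescriptorReport:
    """Run the global pipeline over records, collecting per-record errors.

    Failing records become entries in ``report.errors``; surviving rows
    keep input order.
    """
    cfg = config or ToolkitConfig()
    rows: list[dict] = []
    errors: list[dict] = []
    for record in records:
        try:
            ds = describe(record, pka_model=cfg.pka_model, hc=cfg.hc_ev_nm)
        except CdftError as exc:
            errors.append({"molecule": record.label, "error": str(exc)})
            continue
        row = report_global_row(ds, cfg)
        row["epsilon_homo"] = record.epsilon_homo
        row["epsilon_lumo"] = record.epsilon_lumo
        rows.append({k: row.get(k) for k in GLOBAL_COLUMNS})
    meta = cfg.as_metadata()
    meta["n_inputs"] = len(rows) + len(errors)
    return DescriptorReport(rows=rows, errors=errors, metadata=meta)


def global_report_frame(report: DescriptorReport) -> pd.DataFrame:
    return pd.DataFrame(report.rows, columns=GLOBAL_COLUMNS)


def write_global_csv(report: DescriptorReport, path: Union[str, Path]) -> Path:
    path = Path(path)
    global_report_frame(report).to_csv(path, index=False)
    return path


def site_report_frame(
    table: CondensedSiteTable, decimals: int = DESCRIPTOR_DECIMALS
) -> pd.DataFrame:
    """Site table in the published layout (Δf×100, Parr columns)."""
    df = table.data.copy()
    out = pd.DataFrame({"atom_index": df["atom_index"], "element": df["element"]})
    for col in ("f_plus", "f_minus", "parr_plus", "parr_minus"):
        out[col] = [
            None if pd.isna(v) else round_reported(float(v), decimals) for v in df[col]
        ]
    out["dual_scaled"] = [
        None if pd.isna(v) else round_reported(float(v), 2) for v in df["dual_scaled"]
    ]
    return out[SITE_REPORT_COLUMNS]


def write_site_csv(
    table: CondensedSiteTable,
    path: Union[str, Path],
    footer: Optional[dict] = None,
) -> Path:
    """Write a site report; ``footer`` entries become trailing comments."""
    path = Path(path)
    frame = site_report_frame(table)
    text = frame.to_csv(index=False)
    if footer:
        text += "".join(f"# {key} = {value}\n" for key, value in footer.items())
    path.write_text(text)
    return path
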