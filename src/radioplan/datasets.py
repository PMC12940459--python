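"""Packaged parameter sets and the reference cohort table.

The TSV fixtures under ``radioplan/data`` hold the published Poisson-TCP
parameter sets (primary set 1 and the two sensitivity sets for alternative
alpha/beta values), the relative-seriality NTCP parameters per organ at
risk, the 17-case cohort structure-volume table, and the protocol
dose-volume constraints on both the 20-fraction physical and the EQD2 dose
scales.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List

import numpy as np
import pandas as pd

from .evaluation import ClinicalConstraint
from .radbio import NTCPParams, TCPParams

__all__ = [
    "cohort_fixture",
    "tcp_parameter_table",
    "tcp_parameter_set",
    "ntcp_parameter_table",
    "ntcp_parameter_set",
    "clinical_constraints",
    "TARGET_STRUCTURES",
    "OAR_STRUCTURES",
]

#: Canonical target-volume names, in dose-escalation order (boost first).
TARGET_STRUCTURES = ("gtv_union", "prostate_minus", "ctv_minus")

#: Canonical organ-at-risk names (femoral heads carried as two structures).
OAR_STRUCTURES = (
    "bladder",
    "rectum",
    "sigmoid_colon",
    "small_bowel",
    "penile_bulb",
    "femoral_head_left",
    "femoral_head_right",
)


def _read(name: str, **kwargs) -> pd.DataFrame:
    path = resources.files("radioplan.data").joinpath(name)
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#", **kwargs)


def cohort_fixture() -> pd.DataFrame:
    """The 17-case cohort table of target-structure volumes (cm^3) and the
    GTV-to-prostate volume fraction (%)."""
    df = _read("cohort.tsv")
    assert len(df) == 17
    return df


def tcp_parameter_table(set_id: int | None = None) -> pd.DataFrame:
    """TCP parameter sets with 95% CI columns where published."""
    df = _read("tcp_params.tsv")
    if set_id is not None:
        df = df[df["set"] == set_id].reset_index(drop=True)
        if df.empty:
            raise KeyError(f"unknown TCP parameter set {set_id!r}")
    return df


def tcp_parameter_set(set_id: int = 1) -> Dict[str, TCPParams]:
    """Per-target :class:`~radioplan.radbio.TCPParams` for one set."""
    df = tcp_parameter_table(set_id)
    return {
        row["structure"]: TCPParams(
            rho=float(row["rho"]),
            alpha=float(row["alpha"]),
            alpha_beta=float(row["alpha_beta"]),
        )
        for _, row in df.iterrows()
    }


def ntcp_parameter_table() -> pd.DataFrame:
    """Relative-seriality parameters per organ at risk, as published."""
    return _read("ntcp_params.tsv")


def ntcp_parameter_set(structures=OAR_STRUCTURES) -> Dict[str, NTCPParams]:
    """Per-OAR :class:`~radioplan.radbio.NTCPParams`.

    The published femoral-head row serves both the left and right
    structures.
    """
    df = ntcp_parameter_table().set_index("structure")
    out: Dict[str, NTCPParams] = {}
    for name in structures:
        key = "femoral_heads" if name.startswith("femoral_head") else name
        row = df.loc[key]
        out[name] = NTCPParams(
            d50=float(row["d50"]),
            gamma=float(row["gamma"]),
            alpha_beta=float(row["alpha_beta"]),
            seriality=float(row["seriality"]),
        )
    return out


def clinical_constraints(constraint_set: str = "physical_20fx") -> List[ClinicalConstraint]:
    """Protocol constraints for the selected dose scale
    (``physical_20fx`` or ``eqd2``)."""
    df = _read("constraints.tsv")
    sel = df[df["constraint_set"] == constraint_set]
    if sel.empty:
        raise KeyError(f"unknown constraint set {constraint_set!r}")
    out = []
    for _, row in sel.iterrows():
        out.append(
            ClinicalConstraint(
                structure=row["structure"],
                kind=row["kind"],
                op=row["op"],
                limit=float(row["limit"]),
                unit=row["unit"],
                dose_gy=None if pd.isna(row["dose_gy"]) else float(row["dose_gy"]),
                volume_pct=None
                if pd.isna(row["volume_pct"])
                else float(row["volume_pct"]),
            )
        )
    return out
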