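"""Quantitative polymorph-vs-polymorph comparison.

Range-restricted rigid superposition RMSD between single molecules of two
fibril models, and per-residue circular torsion-angle differencing with
bundle standard deviations.  The superposition range and the scoring range
are independent (published comparisons sometimes align on one residue range
but report RMSD over another).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .geometry import circular_diff_deg, superpose
from .model_io import BACKBONE_ATOMS, FibrilModel

__all__ = ["ComparisonReport", "superpose_rmsd", "torsion_difference"]

_SELECTIONS = ("heavy", "backbone", "ca")


@dataclass(frozen=True)
class ComparisonReport:
    """Result of one range-restricted superposition."""

    rmsd: float  # angstroms, over the scoring selection
    n_atoms: int  # scored atoms
    n_fit_atoms: int
    coverage: float  # matched fraction of the smaller scoring selection
    fit_range: tuple[int, int] | None
    score_range: tuple[int, int] | None
    selection: str
    mismatched_residues: tuple[int, ...] = ()


def _select(m: FibrilModel, chain: str, model: int,
            rng: tuple[int, int] | None, selection: str) -> pd.DataFrame:
    df = m.chain_atoms(chain, model, heavy_only=True)
    if rng is not None:
        df = df[(df["resseq"] >= rng[0]) & (df["resseq"] <= rng[1])]
    if selection == "backbone":
        df = df[df["atom"].isin(BACKBONE_ATOMS)]
    elif selection == "ca":
        df = df[df["atom"] == "CA"]
    elif selection != "heavy":
        raise InsufficientDataError(f"unknown selection {selection!r}; use {_SELECTIONS}")
    return df


def _matched(da: pd.DataFrame, db: pd.DataFrame):
    ia = {(int(r), a): k for k, (r, a) in enumerate(zip(da["resseq"], da["atom"]))}
    ib = {(int(r), a): k for k, (r, a) in enumerate(zip(db["resseq"], db["atom"]))}
    keys = sorted(k for k in ia if k in ib)
    xa = da[["x", "y", "z"]].to_numpy(float)[[ia[k] for k in keys]]
    xb = db[["x", "y", "z"]].to_numpy(float)[[ib[k] for k in keys]]
    return xa, xb, keys


def superpose_rmsd(a: FibrilModel, b: FibrilModel,
                   chain_a: str | None = None, chain_b: str | None = None,
                   fit_range: tuple[int, int] | None = None,
                   score_range: tuple[int, int] | None = None,
                   selection: str = "heavy",
                   bundle: str = "first") -> ComparisonReport:
    """Optimal-superposition RMSD between one molecule of each model.

    Atoms are matched by residue number + atom name; residues whose types
    differ between the models are reported and scored on the intersection of
    their atom names.  The rotation is fitted on ``fit_range`` (least
    squares, proper rotation) and the RMSD evaluated over ``score_range``
    (both default to the full common range).  ``bundle="first"`` compares the
    first bundle member of each model; ``"average"`` averages the RMSD over
    all bundle-member pairs.
    """
    if score_range is None:
        score_range = fit_range
    chain_a = chain_a or a.chains[0]
    chain_b = chain_b or b.chains[0]
    models_a = [a.models[0]] if bundle == "first" else a.models
    models_b = [b.models[0]] if bundle == "first" else b.models
    rmsds = []
    report = None
    for ma, mb in product(models_a, models_b):
        da_fit = _select(a, chain_a, ma, fit_range, selection)
        db_fit = _select(b, chain_b, mb, fit_range, selection)
        xa, xb, keys = _matched(da_fit, db_fit)
        if len(keys) < 3:
            raise InsufficientDataError(
                f"only {len(keys)} matched atoms in the fit range; need >= 3")
        t, _ = superpose(xa, xb)
        da_sc = _select(a, chain_a, ma, score_range, selection)
        db_sc = _select(b, chain_b, mb, score_range, selection)
        ya, yb, skeys = _matched(da_sc, db_sc)
        if len(skeys) < 1:
            raise InsufficientDataError("no matched atoms in the scoring range")
        diff = t.apply(ya) - yb
        rmsds.append(float(np.sqrt(np.mean(np.sum(diff * diff, axis=1)))))
        if report is None:
            mism = _mismatched_residues(da_sc, db_sc)
            denom = min(len(da_sc), len(db_sc))
            report = (len(skeys), len(keys), len(skeys) / denom if denom else 0.0,
                      mism)
    n_sc, n_fit, cov, mism = report
    return ComparisonReport(rmsd=float(np.mean(rmsds)), n_atoms=n_sc,
                            n_fit_atoms=n_fit, coverage=cov,
                            fit_range=fit_range, score_range=score_range,
                            selection=selection, mismatched_residues=mism)


def _mismatched_residues(da: pd.DataFrame, db: pd.DataFrame) -> tuple[int, ...]:
    na = dict(zip(da["resseq"].astype(int), da["resname"]))
    nb = dict(zip(db["resseq"].astype(int), db["resname"]))
    return tuple(sorted(r for r in na.keys() & nb.keys() if na[r] != nb[r]))


def torsion_difference(ta, tb, chains_a: list[str] | None = None,
                       chains_b: list[str] | None = None) -> pd.DataFrame:
    """Per-residue circular phi/psi differences between two torsion tables.

    Inputs are :class:`~crossbeta.conform.TorsionTable` objects; bundle
    means are compared and the combined standard deviation
    ``sqrt(sd_a^2 + sd_b^2)`` flags residues whose difference exceeds it
    (``sig_phi`` / ``sig_psi``) -- conformations that are similar but not
    identical show a handful of such residues.  Disjoint resolved ranges
    give an empty frame.
    """
    sa = ta.bundle_stats(chains=chains_a)
    sb = tb.bundle_stats(chains=chains_b)
    merged = sa.merge(sb, on="resseq", suffixes=("_a", "_b"))
    if merged.empty:
        return pd.DataFrame(columns=["resseq", "dphi", "dpsi", "sd_phi", "sd_psi",
                                     "sig_phi", "sig_psi"])
    out = pd.DataFrame({"resseq": merged["resseq"]})
    out["dphi"] = circular_diff_deg(merged["phi_mean_a"].to_numpy(),
                                    merged["phi_mean_b"].to_numpy())
    out["dpsi"] = circular_diff_deg(merged["psi_mean_a"].to_numpy(),
                                    merged["psi_mean_b"].to_numpy())
    out["sd_phi"] = np.hypot(merged["phi_sd_a"], merged["phi_sd_b"])
    out["sd_psi"] = np.hypot(merged["psi_sd_a"], merged["psi_sd_b"])
    # 1e-3 deg floor so zero-SD (single-model) comparisons do not flag
    # floating-point residue
    out["sig_phi"] = np.abs(out["dphi"]) > np.maximum(out["sd_phi"], 1e-3)
    out["sig_psi"] = np.abs(out["dpsi"]) > np.maximum(out["sd_psi"], 1e-3)
    return out
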