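"""Predicted methane and feed-efficiency traits from fattening records.

Enteric methane is expensive to measure directly, so daily methane
production and yield are predicted from on-farm measurable traits over the
fattening period: mean body weight (BW, kg), average daily gain (DG,
kg/day), dry matter intake (DMI, kg/day), total digestible nutrients as a
percentage of DMI (TDN, %) and the roughage fraction of DMI (Rrate, %).

Two prediction equations are used for daily methane volume: a multi-trait
linear equation (CH4) and the national-inventory quadratic in DMI (CH4S).
Methane yield is expressed per kg of intake (CH4/DMI) and as the methane
conversion factor MCF (% of gross energy intake lost as methane, predicted
by its own regression; gross energy itself is never computed).

Feed-efficiency traits follow the Koch residual convention: residual feed
intake (RFI) is the residual of DMI on metabolic body weight BW^0.75 and
DG; residual gain (RG) the residual of DG on BW^0.75 and DMI; RIG is the
standardized difference z(RG) - z(RFI); FCR = DMI/DG.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BASE_TRAITS = ["BW", "DG", "DMI", "TDN", "Rrate"]
METHANE_TRAITS = ["CH4", "CH4S", "CH4_per_DMI", "MCF"]
EFFICIENCY_TRAITS = ["FCR", "RFI", "RG", "RIG"]

#: Prediction-equation coefficients: intercept and per-predictor slopes.
CH4_COEF = {"intercept": -676.7, "BW": 0.04194, "DMI": 29.88, "TDN": 7.883, "Rrate": 4.367}
CH4_PER_DMI_COEF = {"intercept": -52.24, "BW": -1.193e-3, "DG": -5.905, "TDN": 1.077, "Rrate": 0.5008}
MCF_COEF = {"intercept": -11.43, "BW": -5.308e-4, "DG": -1.223, "TDN": 0.2336, "Rrate": 0.1157}
CH4S_COEF = {"intercept": -17.766, "DMI": 42.793, "DMI2": -0.849}


def predict_ch4s(dmi):
    """National-inventory quadratic: CH4S (L/day) from DMI (kg/day)."""
    dmi = np.asarray(dmi, dtype=float)
    return CH4S_COEF["intercept"] + CH4S_COEF["DMI"] * dmi + CH4S_COEF["DMI2"] * dmi**2


def predict_methane(base: pd.DataFrame) -> pd.DataFrame:
    """Predicted methane traits from a table of base traits.

    Parameters
    ----------
    base : DataFrame
        Must contain columns BW, DG, DMI, TDN, Rrate.

    Returns
    -------
    DataFrame with columns CH4, CH4S, CH4_per_DMI, MCF (index preserved).
    """
    b = base
    out = pd.DataFrame(index=b.index)
    out["CH4"] = (
        CH4_COEF["intercept"]
        + CH4_COEF["BW"] * b["BW"]
        + CH4_COEF["DMI"] * b["DMI"]
        + CH4_COEF["TDN"] * b["TDN"]
        + CH4_COEF["Rrate"] * b["Rrate"]
    )
    out["CH4S"] = predict_ch4s(b["DMI"].to_numpy())
    out["CH4_per_DMI"] = (
        CH4_PER_DMI_COEF["intercept"]
        + CH4_PER_DMI_COEF["BW"] * b["BW"]
        + CH4_PER_DMI_COEF["DG"] * b["DG"]
        + CH4_PER_DMI_COEF["TDN"] * b["TDN"]
        + CH4_PER_DMI_COEF["Rrate"] * b["Rrate"]
    )
    out["MCF"] = (
        MCF_COEF["intercept"]
        + MCF_COEF["BW"] * b["BW"]
        + MCF_COEF["DG"] * b["DG"]
        + MCF_COEF["TDN"] * b["TDN"]
        + MCF_COEF["Rrate"] * b["Rrate"]
    )
    return out


def summarize_fattening(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse longitudinal fattening records to per-animal base traits.

    Expects one row per animal x occasion with columns: ``animal_id``,
    ``day`` (days on test), ``body_weight`` (kg), ``concentrate_dmi``
    (kg/day, individual), ``roughage_dmi`` (kg/day, herd-unit mean),
    ``tdn_concentrate_pct`` and ``tdn_roughage_pct``.

    BW is the interval-length-weighted mean of successive body-weight
    midpoints; DG = (final - initial BW)/elapsed days; DMI = mean daily
    concentrate + roughage intake; TDN and Rrate are aggregated on the same
    daily basis.  Animals with a single occasion are excluded and flagged
    in the ``n_occasions``/``included`` columns.
    """
    rows = []
    for animal, g in records.groupby("animal_id", sort=False):
        g = g.sort_values("day")
        day = g["day"].to_numpy(dtype=float)
        bw = g["body_weight"].to_numpy(dtype=float)
        if len(g) < 2 or day[-1] == day[0]:
            rows.append({"animal_id": animal, "n_occasions": len(g), "included": False})
            continue
        dt = np.diff(day)
        mid = 0.5 * (bw[:-1] + bw[1:])
        bw_mean = float(np.sum(mid * dt) / np.sum(dt))
        dg = float((bw[-1] - bw[0]) / (day[-1] - day[0]))
        conc = g["concentrate_dmi"].to_numpy(dtype=float)
        rough = g["roughage_dmi"].to_numpy(dtype=float)
        # intakes are daily rates observed at occasions; use interval-weighted
        # means of successive midpoints on the same daily basis as BW
        conc_mean = float(np.sum(0.5 * (conc[:-1] + conc[1:]) * dt) / np.sum(dt))
        rough_mean = float(np.sum(0.5 * (rough[:-1] + rough[1:]) * dt) / np.sum(dt))
        dmi = conc_mean + rough_mean
        tdn_c = g["tdn_concentrate_pct"].to_numpy(dtype=float)
        tdn_r = g["tdn_roughage_pct"].to_numpy(dtype=float)
        tdn_flow = 0.5 * ((conc * tdn_c + rough * tdn_r)[:-1] + (conc * tdn_c + rough * tdn_r)[1:])
        tdn = float(np.sum(tdn_flow * dt) / np.sum(dt) / dmi)
        rrate = 100.0 * rough_mean / dmi
        rows.append(
            {
                "animal_id": animal,
                "n_occasions": len(g),
                "included": True,
                "BW": bw_mean,
                "DG": dg,
                "DMI": dmi,
                "TDN": tdn,
                "Rrate": rrate,
            }
        )
    return pd.DataFrame(rows).set_index("animal_id")


def compute_feed_efficiency(base: pd.DataFrame) -> pd.DataFrame:
    """Koch-style feed-efficiency traits from a base-trait table.

    RFI = residual of OLS DMI ~ BW^0.75 + DG; RG = residual of
    DG ~ BW^0.75 + DMI; RIG = z(RG) - z(RFI); FCR = DMI/DG (missing when
    DG <= 0).  Requires >= 30 animals for a stable regression.
    """
    if len(base) < 30:
        raise ValueError("feed-efficiency regressions need >= 30 animals")
    mbw = base["BW"].to_numpy(dtype=float) ** 0.75
    dg = base["DG"].to_numpy(dtype=float)
    dmi = base["DMI"].to_numpy(dtype=float)
    ones = np.ones_like(dg)

    def resid(y, covs):
        X = np.column_stack([ones, *covs])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    out = pd.DataFrame(index=base.index)
    out["FCR"] = np.where(dg > 0, dmi / np.where(dg > 0, dg, np.nan), np.nan)
    rfi = resid(dmi, [mbw, dg])
    rg = resid(dg, [mbw, dmi])
    out["RFI"] = rfi
    out["RG"] = rg
    out["RIG"] = (rg - rg.mean()) / rg.std(ddof=1) - (rfi - rfi.mean()) / rfi.std(ddof=1)
    return out


def filter_3sd(values) -> np.ndarray:
    """Inclusion mask keeping values within mean +/- 3 SD.

    Mean and SD are computed once on the non-missing values (single pass,
    not iterated); missing values get a False mask.  A constant vector is
    fully retained (SD = 0, deviations 0).
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        return np.zeros_like(ok)
    mu = x[ok].mean()
    sd = x[ok].std(ddof=1)
    mask = np.zeros_like(ok)
    mask[ok] = np.abs(x[ok] - mu) <= 3.0 * sd
    return mask


def apply_3sd_filter(table: pd.DataFrame, traits: list[str] | None = None) -> pd.DataFrame:
    """Mask per-trait outliers (each trait filtered independently, once)."""
    out = table.copy()
    for t in traits or [c for c in table.columns if table[c].dtype.kind == "f"]:
        keep = filter_3sd(out[t].to_numpy())
        out.loc[~keep, t] = np.nan
    return out
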