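"""Table-style reports: observed ratios with best-fitting classical models,
and observed-versus-model expectations with chi-square significance."""

from __future__ import annotations

import pandas as pd

from . import fit as ft
from .model import ModelParams, STANDARD_CHAINS, chain_h_prob


def table1_report(observed: pd.DataFrame, degenerate_tol: float = 0.06) -> pd.DataFrame:
    """Best-fitting classical segregation ratio per observed cross row.

    ``observed`` needs columns cross, n_h, n_ms (a year column is carried
    through when present).  The fractional degenerate tolerance admits 1:0 /
    0:1 for rows with only a few off-class plants.
    """
    rows = []
    for _, r in observed.iterrows():
        counts = ft.SegCounts(str(r["cross"]), int(r["n_h"]), int(r["n_ms"]))
        res = ft.classic_ratio_fit(counts, degenerate_tol=degenerate_tol)
        best_gof = dict(res.scores).get(res.best)
        rows.append(
            {
                "cross": counts.label,
                **({"year": r["year"]} if "year" in observed.columns else {}),
                "n_H": counts.n_h,
                "n_MS": counts.n_ms,
                "best_ratio": res.best.label,
                "chi2": None if best_gof is None else round(best_gof.chi2, 3),
                "p": None if best_gof is None else round(best_gof.p, 4),
            }
        )
    return pd.DataFrame(rows)


#: Observed cells of the model-comparison table: F2 and BC1 of the main
#: family plus BC2 progeny of hermaphrodite BC1 mothers.
MODEL_TABLE_OBSERVED = (
    ("F2", 550, 144),
    ("BC1", 71, 42),
    ("BC2(H)", 528, 503),
)


def _stars(p: float) -> str:
    return "*" if p < 0.001 else "n.s."


def table2_report(
    tau: float = 0.575,
    restoration: float = 0.4,
    observed=MODEL_TABLE_OBSERVED,
) -> pd.DataFrame:
    """Observed H:MS versus the one-restorer-locus model's expectations.

    Model A: strictly dominant restorer (no restoration of mm plants).
    Model B: dominant restorer with partial restoration of the nonrestorer
    homozygote (default 40%).  Both use the distorted transmission tau.
    """
    model_a = ModelParams(tau=tau, r_r=0.0, r_n=0.0)
    model_b = ModelParams(tau=tau, r_r=restoration, r_n=restoration)
    rows = []
    for label, n_h, n_ms in observed:
        chain = STANDARD_CHAINS[label]()
        obs = ft.SegCounts(label, n_h, n_ms, chain)
        row = {"cross": label, "observed": f"{n_h}:{n_ms}", "df": 1}
        for tag, params in (("A", model_a), ("B", model_b)):
            exp = ft.expected_counts(chain_h_prob(chain, params), obs.n)
            gof = ft.gof_chi2(obs, exp)
            row[f"expected_{tag}"] = f"{exp.h_int}:{exp.ms_int}"
            row[f"chi2_{tag}"] = round(gof.chi2, 2)
            row[f"sig_{tag}"] = _stars(gof.p)
        rows.append(row)
    return pd.DataFrame(rows)
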