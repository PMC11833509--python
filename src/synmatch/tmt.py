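"""Per-protein linear modelling of six-plex TMT ratios with moderated t statistics.

The quantitative design has three groups of TMT channels: bait proximity
labeling (TRT), a membrane-anchored spatial reference (SR), and a negative
control with a labeling reagent omitted (NC).  For each protein the log2
TMT ratio is modelled as

    log2ratio = b0 + b1*TRT + b2*SR

with TRT and SR indicator variables and NC the baseline.  The bait/NC log2
fold change is ``b1``; the bait/SR fold change is the contrast ``b1 - b2``.
Residual variances are shrunk toward a prior variance ``s0_sq`` with prior
degrees of freedom ``d0`` estimated across proteins by method of moments on
the log sample variances, and each contrast is tested with a moderated t
statistic on ``d0 + df`` degrees of freedom.  Nominal p-values are adjusted
with the Benjamini-Hochberg step-up procedure, separately per contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

META_COLUMNS = ("protein_id", "gene_symbol", "unique_peptides")


class Group(str, Enum):
    """Channel group: bait labeling, spatial reference, or negative control."""

    TRT = "TRT"
    SR = "SR"
    NC = "NC"


@dataclass(frozen=True)
class TmtChannel:
    label: str
    group: Group
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class TmtDesign:
    """Ordered channel -> group assignment for one TMT run.

    Requires at least one channel per group and at least one residual
    degree of freedom (n_channels - 3 >= 1).
    """

    channels: tuple[TmtChannel, ...]

    def __post_init__(self) -> None:
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        present = {c.group for c in self.channels}
        missing = set(Group) - present
        if missing:
            raise ValueError(
                "every group needs >=1 channel; missing: "
                + ", ".join(sorted(g.value for g in missing))
            )
        if len(self.channels) - 3 < 1:
            raise ValueError("need n_channels - 3 >= 1 residual df")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    @property
    def groups(self) -> np.ndarray:
        return np.array([c.group.value for c in self.channels])

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def residual_df(self) -> int:
        return self.n_channels - 3

    def design_matrix(self) -> np.ndarray:
        """Columns: intercept, TRT indicator, SR indicator (NC is baseline)."""
        g = self.groups
        return np.column_stack(
            [
                np.ones(len(g)),
                (g == Group.TRT.value).astype(float),
                (g == Group.SR.value).astype(float),
            ]
        )

    def contrast_vector(self, contrast: Literal["NC", "SR"]) -> np.ndarray:
        """Contrast picking the bait/NC (b1) or bait/SR (b1 - b2) fold change."""
        if contrast == "NC":
            return np.array([0.0, 1.0, 0.0])
        if contrast == "SR":
            return np.array([0.0, 1.0, -1.0])
        raise ValueError(f"unknown contrast {contrast!r}")

    def unscaled_contrast_variance(self, contrast: Literal["NC", "SR"]) -> float:
        """c' (X'X)^{-1} c; equals 1 for both contrasts on a balanced 2/2/2 design."""
        X = self.design_matrix()
        c = self.contrast_vector(contrast)
        return float(c @ np.linalg.solve(X.T @ X, c))

    @classmethod
    def from_dict(cls, spec: dict) -> "TmtDesign":
        chans = []
        for entry in spec["channels"]:
            chans.append(
                TmtChannel(
                    label=str(entry["label"]),
                    group=Group(entry["group"]),
                    replicate=int(entry.get("replicate", 1)),
                )
            )
        return cls(tuple(chans))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TmtDesign":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "channels": [
                {"label": c.label, "group": c.group.value, "replicate": c.replicate}
                for c in self.channels
            ]
        }


def default_design() -> TmtDesign:
    """The balanced 2/2/2 six-plex design: two channels per group."""
    return TmtDesign(
        tuple(
            TmtChannel(f"{g}_{r}", Group(g), r)
            for g in ("TRT", "SR", "NC")
            for r in (1, 2)
        )
    )


@dataclass(frozen=True)
class EBayesPrior:
    """Prior variance s0_sq with d0 prior degrees of freedom (d0 = inf allowed)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 >= 0):
            raise ValueError(f"d0 must be >= 0 or inf, got {self.d0}")
        if not (self.s0_sq > 0):
            raise ValueError(f"s0_sq must be > 0, got {self.s0_sq}")

    @property
    def is_infinite(self) -> bool:
        return np.isinf(self.d0)


@dataclass
class NormalizationReport:
    """Audit trail of records rejected or dropped during ratio conversion."""

    n_in: int = 0
    n_out: int = 0
    rejected: list[tuple[str, str]] = field(default_factory=list)
    n_dropped_all_missing: int = 0


def read_quant_table(
    path: str | Path,
    design: TmtDesign,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a protein quantification TSV/CSV.

    ``column_map`` maps canonical names (``protein_id``, ``gene_symbol``,
    ``unique_peptides`` and each design channel label) to the file's column
    names when they differ.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    required = list(META_COLUMNS) + design.labels
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"quant table missing columns: {missing}")
    return df[required].copy()


def normalize_to_log2_ratios(
    table: pd.DataFrame,
    design: TmtDesign,
    mode: Literal["raw_intensity", "precomputed"] = "raw_intensity",
) -> tuple[pd.DataFrame, NormalizationReport]:
    """Convert reporter intensities to log2 ratios.

    In ``raw_intensity`` mode each protein's channel value becomes
    ``log2(intensity / median intensity across its channels)``, after which
    each channel is median-centered across proteins to remove loading
    differences.  ``precomputed`` mode returns the table unchanged (values
    are already log2 ratios).

    Proteins with any nonpositive intensity (raw mode) are rejected;
    all-missing proteins are dropped.  Both are counted in the report.
    """
    report = NormalizationReport(n_in=len(table))
    if mode == "precomputed":
        report.n_out = len(table)
        return table.copy(), report
    if mode != "raw_intensity":
        raise ValueError(f"unknown mode {mode!r}")

    labels = design.labels
    vals = table[labels].to_numpy(dtype=float)
    all_missing = np.all(~np.isfinite(vals), axis=1)
    nonpositive = np.any(np.isfinite(vals) & (vals <= 0), axis=1)
    keep = ~(all_missing | nonpositive)
    report.n_dropped_all_missing = int(all_missing.sum())
    for pid in table.loc[nonpositive & ~all_missing, "protein_id"]:
        report.rejected.append((str(pid), "nonpositive intensity in raw mode"))
    if report.rejected:
        logger.warning(
            "rejected %d proteins with nonpositive intensities", len(report.rejected)
        )
    if report.n_dropped_all_missing:
        logger.warning(
            "dropped %d proteins with all channels missing",
            report.n_dropped_all_missing,
        )

    out = table.loc[keep].copy()
    v = out[labels].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(v, axis=1, keepdims=True)
        log_ratio = np.log2(v / med)
    # channel-wise median centering across proteins (loading normalization)
    log_ratio = log_ratio - np.nanmedian(log_ratio, axis=0, keepdims=True)
    out[labels] = log_ratio
    report.n_out = len(out)
    return out, report


def fit_protein_models(table: pd.DataFrame, design: TmtDesign) -> pd.DataFrame:
    """OLS fit of the indicator model per protein.

    Returns one row per fitted protein with ``b0, b1, b2, s2, df, fc_nc,
    fc_sr``.  For a balanced design the coefficients reduce to b0 = mean(NC),
    b1 = mean(TRT) - mean(NC), b2 = mean(SR) - mean(NC).  Proteins whose
    missing channels leave a group empty or residual df < 1 are dropped and
    logged.
    """
    labels = design.labels
    X_full = design.design_matrix()
    groups = design.groups
    vals = table[labels].to_numpy(dtype=float)

    rows = []
    n_dropped = 0
    for i in range(len(table)):
        y = vals[i]
        ok = np.isfinite(y)
        df_resid = int(ok.sum()) - 3
        present = set(groups[ok])
        if df_resid < 1 or len(present) < 3:
            n_dropped += 1
            continue
        X = X_full[ok]
        y_ok = y[ok]
        beta, *_ = np.linalg.lstsq(X, y_ok, rcond=None)
        resid = y_ok - X @ beta
        s2 = float(resid @ resid) / df_resid
        rows.append(
            {
                "protein_id": table["protein_id"].iloc[i],
                "gene_symbol": table["gene_symbol"].iloc[i],
                "unique_peptides": table["unique_peptides"].iloc[i],
                "b0": beta[0],
                "b1": beta[1],
                "b2": beta[2],
                "s2": s2,
                "df": df_resid,
                "fc_nc": beta[1],
                "fc_sr": beta[1] - beta[2],
            }
        )
    if n_dropped:
        logger.warning(
            "dropped %d proteins unidentifiable after channel deletion", n_dropped
        )
    return pd.DataFrame(rows)


def fit_single_protein(y: Sequence[float], design: TmtDesign) -> dict:
    """Fit one protein's log2 ratios; convenience wrapper around the table fit.

    Raises if a design group has no finite observation (rank-deficient model).
    """
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    for g in Group:
        if not np.any(ok & (design.groups == g.value)):
            raise ValueError(f"group {g.value} has no observations; model rank-deficient")
    tab = pd.DataFrame([{"protein_id": "p", "gene_symbol": "p", "unique_peptides": 2}])
    for lab, v in zip(design.labels, y):
        tab[lab] = v
    fits = fit_protein_models(tab, design)
    if fits.empty:
        raise ValueError("residual df < 1; model unidentifiable")
    return fits.iloc[0].to_dict()


def _trigamma_inverse(x: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    trigamma is decreasing and convex on (0, inf); the iteration below (in
    1/y space) converges monotonically from the asymptotic start y ~ 1/x.
    """
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return y


def estimate_eb_prior(
    s2: Iterable[float],
    df: Iterable[float],
    min_proteins: int = 10,
) -> EBayesPrior:
    """Method-of-moments estimate of (d0, s0_sq) from residual variances.

    Uses the log-variance moments: for each protein, ``e_g = log s2_g -
    digamma(df_g/2) + log(df_g/2)`` is an unbiased estimate of ``log s0_sq
    + digamma(d0/2) - log(d0/2)`` with variance ``trigamma(df_g/2) +
    trigamma(d0/2)``.  d0 is recovered by inverting trigamma on the excess
    spread of ``e_g``; a non-positive excess flags d0 infinite (no
    between-protein variance heterogeneity beyond sampling noise).

    Proteins with s2 <= 0 or df < 1 are excluded from estimation (they are
    still moderated downstream).
    """
    s2 = np.asarray(list(s2), dtype=float)
    df = np.asarray(list(df), dtype=float)
    ok = (s2 > 0) & (df >= 1) & np.isfinite(s2)
    s2, df = s2[ok], df[ok]
    n = len(s2)
    if n < min_proteins:
        raise ValueError(f"need >= {min_proteins} proteins with s2 > 0, got {n}")

    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(np.mean(e))
    excess = float(
        np.mean((e - e_bar) ** 2) * n / (n - 1) - np.mean(special.polygamma(1, df / 2.0))
    )
    if excess <= 0:
        # no excess spread: all proteins share one variance; the arithmetic
        # mean is the natural scale (and equals the common value when all
        # variances are identical)
        return EBayesPrior(d0=np.inf, s0_sq=float(np.mean(s2)))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def posterior_variance(s2: np.ndarray, df: np.ndarray, prior: EBayesPrior) -> np.ndarray:
    """Shrunken variance s~2 = (d0*s0_sq + df*s2) / (d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    if prior.is_infinite:
        return np.full_like(s2, prior.s0_sq)
    return (prior.d0 * prior.s0_sq + df * s2) / (prior.d0 + df)


def moderated_t(
    estimate: float | np.ndarray,
    s2: float | np.ndarray,
    df: float | np.ndarray,
    prior: EBayesPrior,
    unscaled_variance: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t statistic, two-sided p, and total df for a contrast.

    ``estimate`` is the contrast estimate c'beta, ``unscaled_variance`` is
    c'(X'X)^{-1}c (1 for both contrasts of the balanced 2/2/2 design).  The
    statistic is estimate / (s~ * sqrt(unscaled_variance)) referred to a
    Student t with d0 + df degrees of freedom; when d0 is infinite the
    reference is standard normal.  With d0 = 0 this is the ordinary OLS t.
    """
    estimate = np.atleast_1d(np.asarray(estimate, dtype=float))
    s2 = np.atleast_1d(np.asarray(s2, dtype=float))
    df = np.atleast_1d(np.asarray(df, dtype=float))
    s2_post = posterior_variance(s2, df, prior)
    se = np.sqrt(s2_post * unscaled_variance)

    t = np.zeros_like(estimate)
    nonzero_est = estimate != 0
    degenerate = (se == 0) & nonzero_est
    if np.any(degenerate):
        warnings.warn(
            "zero posterior variance with nonzero estimate; reporting p = 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, estimate / se, np.where(nonzero_est, np.inf * np.sign(estimate), 0.0))

    df_total = np.where(np.isinf(prior.d0), np.inf, prior.d0 + df)
    p = np.where(
        np.isinf(df_total),
        2.0 * stats.norm.sf(np.abs(t)),
        2.0 * stats.t.sf(np.abs(t), np.where(np.isinf(df_total), 1.0, df_total)),
    )
    p = np.where(degenerate, 0.0, p)
    p = np.where(~nonzero_est, 1.0, p)
    return t, p, df_total


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, q_(i) = min_{j>=i} p_(j)*n/j."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ebayes_fits(
    fits: pd.DataFrame,
    design: TmtDesign,
    prior: EBayesPrior | None = None,
) -> tuple[pd.DataFrame, EBayesPrior]:
    """Attach moderated statistics and per-contrast BH-FDR q-values to fits.

    Adds columns ``t_mod_nc, p_nc, q_nc, t_mod_sr, p_sr, q_sr`` (and the
    prior used).  The two contrasts are adjusted separately.
    """
    out = fits.copy()
    if prior is None:
        prior = estimate_eb_prior(out["s2"], out["df"])
    for contrast, fc_col in (("NC", "fc_nc"), ("SR", "fc_sr")):
        uv = design.unscaled_contrast_variance(contrast)  # type: ignore[arg-type]
        t, p, _ = moderated_t(
            out[fc_col].to_numpy(), out["s2"].to_numpy(), out["df"].to_numpy(), prior, uv
        )
        suffix = contrast.lower()
        out[f"t_mod_{suffix}"] = t
        out[f"p_{suffix}"] = p
        out[f"q_{suffix}"] = bh_fdr(p)
    return out, prior


def analyze_quant_table(
    table: pd.DataFrame,
    design: TmtDesign,
    mode: Literal["raw_intensity", "precomputed"] = "precomputed",
) -> tuple[pd.DataFrame, EBayesPrior, NormalizationReport]:
    """Full model pass: normalize, fit per protein, moderate, FDR-adjust."""
    ratios, report = normalize_to_log2_ratios(table, design, mode=mode)
    fits = fit_protein_models(ratios, design)
    fits, prior = ebayes_fits(fits, design)
    return fits, prior, report
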