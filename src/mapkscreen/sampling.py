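"""Concentration grid, random kinetic-rate sampling, and the ensemble screen.

The concentration design crosses [MAPKK]_total and [MAPK]_total over
{0.2, 1.0, 5.0} (relative to [MAPKKK]_total = 1) with phosphatase totals at
{0.1, 1.0} times their respective substrates: 3 * 3 * 2 * 2 = 36 vectors.
Kinetic-rate vectors are drawn log-uniformly per rate (default range
[0.1, 10], centered on the unit MAPKKK-activation rate); each vector is
evaluated under all three feedback topologies with shared non-feedback
rates, so topology comparisons are paired.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig, SamplingConfig, SolverConfig, Thresholds
from .indicators import (BistabilityResult, DynamicsReport,
                         IndeterminateBistabilityError, bistability_index,
                         classify_temporal, gradient)
from .network import (ConcentrationVector, KineticRates, RATE_NAMES,
                      ReactionNetwork, SPECIES_INDEX, Topology, build_network)
from .simulate import (IntegrationError, NonStationaryError,
                       dose_response_sweep, steady_state_course)

__all__ = [
    "concentration_grid", "sample_rates", "ScreenDesign", "ScreenSummary",
    "run_screen", "robust_rate_vectors", "ratio_grouping", "mapkk_scan",
    "group_by_gradient", "MapkkScanResult",
    "MissingCellsError", "UnknownSelectorError", "InsufficientDataError",
    "DegenerateScanError", "ExcessiveFailureError",
]

_PP_MAPK = SPECIES_INDEX["pp-MAPK"]
_PP_MAPKK = SPECIES_INDEX["pp-MAPKK"]


class MissingCellsError(ValueError):
    """Per-model table does not cover all 36 concentration vectors."""


class UnknownSelectorError(KeyError):
    """Rate/ratio selector not recognized."""


class InsufficientDataError(ValueError):
    """Fewer than three responsive points survive a concentration scan."""


class DegenerateScanError(ValueError):
    """All scan points have identical values; correlation undefined."""


class ExcessiveFailureError(RuntimeError):
    """More than the allowed fraction of models failed to integrate."""


def concentration_grid() -> list[ConcentrationVector]:
    """The 36-vector concentration design, ids 1..36.

    Ordering: [MAPKK]_total outermost, then [MAPK]_total, then the M2KP
    factor, then the MKP factor innermost, so id 1 is
    (0.2, 0.2, 0.02, 0.02) and id 36 is (5, 5, 5, 5).
    """
    grid = []
    for mapkk, mapk, f_m2kp, f_mkp in itertools.product(
            (0.2, 1.0, 5.0), (0.2, 1.0, 5.0), (0.1, 1.0), (0.1, 1.0)):
        grid.append(ConcentrationVector(mapkk, mapk,
                                        round(f_m2kp * mapkk, 12),
                                        round(f_mkp * mapk, 12)))
    return grid


def sample_rates(n: int, seed: int, topology: Topology | str = "positive",
                 sampling: SamplingConfig | None = None) -> list[KineticRates]:
    """Draw ``n`` seeded random rate vectors, log-uniform per rate.

    All 28 values (including the feedback magnitude ``kf``) are drawn for
    every vector regardless of topology; for the no-feedback topology ``kf``
    is then pinned to 0.  The same (n, seed) therefore yields vectors whose
    26 non-feedback rates are shared across topologies.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    topology = Topology.coerce(topology)
    sampling = sampling or SamplingConfig()
    rng = np.random.default_rng(seed)
    lo, hi = np.log10(sampling.low), np.log10(sampling.high)
    draws = 10.0 ** rng.uniform(lo, hi, size=(n, len(RATE_NAMES)))
    out = []
    for row in draws:
        kr = KineticRates.from_array(row)
        out.append(kr.with_kf(0.0) if topology is Topology.NONE else kr)
    return out


@dataclass
class ScreenDesign:
    """Everything that determines a screen: grid, rate vectors, topologies."""

    cvs: list[ConcentrationVector]
    krvs: list[KineticRates]          # feedback draw included; kf zeroed per topology
    topologies: tuple[str, ...] = ("none", "positive", "negative")
    seed: int = 0

    @classmethod
    def generate(cls, n_rate_vectors: int, seed: int,
                 topologies=("none", "positive", "negative"),
                 sampling: SamplingConfig | None = None) -> "ScreenDesign":
        return cls(cvs=concentration_grid(),
                   krvs=sample_rates(n_rate_vectors, seed, "positive", sampling),
                   topologies=tuple(topologies), seed=seed)

    @property
    def size(self) -> int:
        return len(self.cvs) * len(self.krvs) * len(self.topologies)


def _rates_for(krv: KineticRates, topology: Topology) -> KineticRates:
    return krv.with_kf(0.0) if topology is Topology.NONE else krv


def evaluate_model(network: ReactionNetwork, rates: KineticRates,
                   cv: ConcentrationVector, config: RunConfig,
                   *, cv_id: int | None = None, krv_id: int | None = None,
                   full: bool = True,
                   solver: SolverConfig | None = None) -> DynamicsReport:
    """Classify one (concentration vector, rate vector, topology) model.

    Responsiveness and the temporal class come from the saturating-stimulus
    time course; for responsive models (``full=True``) the up-branch
    dose-response yields O_ss_max and Gradient, and a single down-branch
    solve from SCV_max at the check point yields the bistability index.
    """
    th = config.thresholds
    solver = solver or config.solver
    report = DynamicsReport(cv_id=cv_id, krv_id=krv_id,
                            topology=network.topology.value,
                            o_max=0.0, responsive=False)
    quiescent = cv.quiescent_state()
    state, course, status = steady_state_course(network, rates, quiescent,
                                                config.s_max, solver)
    if course is not None:
        report.o_max = float(np.max(course.output))
    elif state is not None:
        report.o_max = float(state[_PP_MAPK] / cv.mapk)
    if status == "oscillating":
        report.status = "non-stationary"
    report.responsive = report.o_max > th.responsive_o_max
    if report.responsive and course is not None:
        report.temporal_class = classify_temporal(course, th)
    if status == "oscillating" and report.responsive:
        report.temporal_class = "oscillation"
    if not (report.responsive and full):
        return report

    try:
        dr = dose_response_sweep(network, rates, cv, config.screen_s_grid(),
                                 solver)
    except IntegrationError:
        raise
    except NonStationaryError:
        report.status = "non-stationary"
        return report
    except Exception:
        report.status = "indeterminate"
        return report
    if dr.up_mask.sum() < 2:
        report.status = "indeterminate"
        return report

    report.o_ss_max = dr.o_ss_max
    try:
        g = gradient(dr, th)
        report.gradient = g.value
        report.ultrasensitive = g.value > th.ultrasensitive_gradient
        b = bistability_index(dr, th)
        report.bistability = b.value
        report.s_cp = b.s_cp
        report.bistable = b.value > th.bistable_index
        report.absolutely_bistable = b.value > th.absolute_bistable_index
    except IndeterminateBistabilityError:
        report.status = "indeterminate"
    except IntegrationError:
        raise
    except Exception:
        report.status = "indeterminate"
    return report


@dataclass
class ScreenSummary:
    """Aggregate screen results.

    ``records``: one row per model evaluation.  ``cell_summary``: per
    (cv_id, topology) counts and the three ratios — r_EA (responsive /
    total), r_SU (ultrasensitive / responsive), r_BI (bistable /
    responsive).  Ratios with zero denominator are null, never 0.
    """

    records: pd.DataFrame
    cell_summary: pd.DataFrame = field(init=False)

    def __post_init__(self):
        self.cell_summary = self._summarize()

    def _summarize(self) -> pd.DataFrame:
        ok = self.records[self.records["status"] != "failed"]
        rows = []
        for (cv_id, topo), grp in ok.groupby(["cv_id", "topology"], sort=True):
            n_total = len(grp)
            n_resp = int(grp["responsive"].sum())
            n_su = int((grp["ultrasensitive"] == True).sum())  # noqa: E712
            n_bi = int((grp["bistable"] == True).sum())  # noqa: E712
            n_abs = int((grp["absolutely_bistable"] == True).sum())  # noqa: E712
            rows.append({
                "cv_id": cv_id, "topology": topo, "N_total": n_total,
                "N_responsive": n_resp, "N_ultrasensitive": n_su,
                "N_bistable": n_bi, "N_absolutely_bistable": n_abs,
                "N_transient": int((grp["temporal_class"] == "transient").sum()),
                "N_oscillation": int((grp["temporal_class"] == "oscillation").sum()),
                "r_EA": n_resp / n_total if n_total else np.nan,
                "r_SU": n_su / n_resp if n_resp else np.nan,
                "r_BI": n_bi / n_resp if n_resp else np.nan,
            })
        return pd.DataFrame(rows)

    # -- pooled statistics -------------------------------------------------
    @property
    def pooled_responsive_fraction(self) -> float:
        ok = self.records[self.records["status"] != "failed"]
        return float(ok["responsive"].mean())

    @property
    def pooled_ultrasensitive_fraction(self) -> float:
        """Fraction of responsive models with Gradient above threshold."""
        resp = self.records[(self.records["status"] != "failed")
                            & self.records["responsive"]
                            & self.records["gradient"].notna()]
        if len(resp) == 0:
            return np.nan
        return float((resp["ultrasensitive"] == True).mean())  # noqa: E712

    @property
    def pooled_bistable_fraction(self) -> float:
        resp = self.records[(self.records["status"] != "failed")
                            & self.records["responsive"]
                            & self.records["bistability"].notna()]
        if len(resp) == 0:
            return np.nan
        return float((resp["bistable"] == True).mean())  # noqa: E712

    def table2(self) -> pd.DataFrame:
        """Per-concentration-vector ratio table (percentages), topology-pooled."""
        ok = self.records[self.records["status"] != "failed"]
        rows = []
        cv_cols = {i + 1: cv for i, cv in enumerate(concentration_grid())}
        for cv_id, grp in ok.groupby("cv_id", sort=True):
            n_total = len(grp)
            n_resp = int(grp["responsive"].sum())
            n_su = int((grp["ultrasensitive"] == True).sum())  # noqa: E712
            n_bi = int((grp["bistable"] == True).sum())  # noqa: E712
            cv = cv_cols.get(cv_id)
            rows.append({
                "id": cv_id,
                "MAPKK": cv.mapkk if cv else np.nan,
                "MAPK": cv.mapk if cv else np.nan,
                "M2KP": cv.m2kp if cv else np.nan,
                "MKP": cv.mkp if cv else np.nan,
                "r_EA_pct": round(100 * n_resp / n_total, 2) if n_total else np.nan,
                "r_SU_pct": round(100 * n_su / n_resp, 2) if n_resp else np.nan,
                "r_BI_pct": round(100 * n_bi / n_resp, 2) if n_resp else np.nan,
            })
        return pd.DataFrame(rows)

    def table3(self) -> pd.DataFrame:
        """Bistable (absolutely bistable) counts per cv and topology."""
        piv = self.cell_summary.pivot_table(
            index="cv_id", columns="topology",
            values=["N_bistable", "N_absolutely_bistable"], aggfunc="sum")
        return piv


def run_screen(design: ScreenDesign, config: RunConfig | None = None,
               *, full: bool = True, records_path: str | Path | None = None,
               solver: SolverConfig | None = None) -> ScreenSummary:
    """Evaluate the whole design and aggregate the screen statistics.

    Deterministic given the design (seeded rate vectors) and config.  With
    ``full=False`` only responsiveness and temporal class are computed (no
    dose-response sweeps).  ``records_path`` enables resumption: per-model
    rows already present in the CSV are skipped and new rows appended.

    Integration failures are logged as status='failed' and excluded from
    denominators; a failure fraction above ``config.max_failure_rate``
    aborts with :class:`ExcessiveFailureError`.
    """
    config = config or RunConfig()
    nets = {t: build_network(t) for t in design.topologies}
    done: set[tuple] = set()
    old_rows: list[dict] = []
    if records_path is not None and Path(records_path).exists():
        prev = pd.read_csv(records_path)
        old_rows = prev.to_dict("records")
        done = {(r["cv_id"], r["krv_id"], r["topology"]) for r in old_rows}

    rows: list[dict] = []
    n_failed = 0
    n_done = 0
    for krv_id, krv in enumerate(design.krvs):
        for topo_name, net in nets.items():
            rates = _rates_for(krv, net.topology)
            for cv_id, cv in enumerate(design.cvs, start=1):
                key = (cv_id, krv_id, topo_name)
                if key in done:
                    continue
                n_done += 1
                try:
                    rep = evaluate_model(net, rates, cv, config,
                                         cv_id=cv_id, krv_id=krv_id,
                                         full=full, solver=solver)
                except IntegrationError:
                    rep = DynamicsReport(cv_id=cv_id, krv_id=krv_id,
                                         topology=topo_name, o_max=np.nan,
                                         responsive=False, status="failed")
                    n_failed += 1
                rows.append(rep.to_row())
    total = max(n_done, 1)
    if n_failed / total > config.max_failure_rate:
        raise ExcessiveFailureError(
            f"{n_failed}/{total} model evaluations failed "
            f"(> {100 * config.max_failure_rate:.0f}% allowed); "
            "check solver settings and sampling range")

    records = pd.DataFrame(old_rows + rows)
    if records_path is not None:
        records.to_csv(records_path, index=False)
    return ScreenSummary(records)


def robust_rate_vectors(per_model_table: pd.DataFrame, min_cases: int = 30,
                        topology: str = "none") -> list[int]:
    """Rate-vector ids responsive for strictly more than ``min_cases`` of 36.

    Requires complete coverage of the 36 concentration vectors for every
    rate vector at the fixed topology.
    """
    tbl = per_model_table[per_model_table["topology"] == topology]
    n_cv = len(concentration_grid())
    missing = []
    for krv_id, grp in tbl.groupby("krv_id"):
        absent = set(range(1, n_cv + 1)) - set(grp["cv_id"])
        if absent:
            missing.append((krv_id, sorted(absent)))
    if missing:
        raise MissingCellsError(f"incomplete coverage: {missing[:5]}"
                                + ("..." if len(missing) > 5 else ""))
    counts = tbl.groupby("krv_id")["responsive"].sum()
    return sorted(int(k) for k, c in counts.items() if c > min_cases)


_RATIO_FAMILIES = {f"kb{s}/kd{s}" for s in ("2", "3", "-3", "-2", "4", "5", "-5", "-4")} \
    | {f"k{s}/k-{s}" for s in ("2", "3", "4", "5")}


def _validate_selector(selector: str) -> None:
    if "/" in selector:
        parts = selector.split("/")
        if selector not in _RATIO_FAMILIES or len(parts) != 2 \
                or any(p not in RATE_NAMES for p in parts):
            raise UnknownSelectorError(selector)
    elif selector not in RATE_NAMES:
        raise UnknownSelectorError(selector)


def _selector_value(rates: KineticRates, selector: str) -> float:
    if "/" in selector:
        num, den = selector.split("/")
        return rates[num] / rates[den]
    return rates[selector]


def ratio_grouping(rate_vectors: list[KineticRates], selector: str,
                   log10_range: tuple[float, float] = (-2.0, 2.0),
                   bin_width: float = 0.5) -> pd.Series:
    """Histogram of a rate or rate-ratio over half-decade log10 bins.

    ``selector`` names either a binding/dissociation or forward/backward
    ratio family (e.g. ``"kb5/kd5"``, ``"k2/k-2"``) or a single rate
    (e.g. ``"k3"``).  Returns counts indexed by bin left edge (log10 scale);
    values outside the range are clipped into the edge bins.
    """
    _validate_selector(selector)
    if not rate_vectors:
        edges = np.arange(log10_range[0], log10_range[1] + bin_width / 2,
                          bin_width)
        return pd.Series(0, index=edges[:-1], name=selector)
    vals = np.array([_selector_value(r, selector) for r in rate_vectors])
    logs = np.log10(vals)
    edges = np.arange(log10_range[0], log10_range[1] + bin_width / 2, bin_width)
    logs = np.clip(logs, edges[0], edges[-1] - 1e-9)
    counts, _ = np.histogram(logs, bins=edges)
    return pd.Series(counts, index=edges[:-1], name=selector)


@dataclass
class MapkkScanResult:
    mapkk_values: np.ndarray
    gradients: np.ndarray
    signal_ranges: np.ndarray
    corr_gradient: float
    corr_signal_range: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def mapkk_scan(network: ReactionNetwork, rates: KineticRates,
               cv: ConcentrationVector, mapkk_values,
               config: RunConfig | None = None,
               solver: SolverConfig | None = None) -> MapkkScanResult:
    """Scan [MAPKK]_total at fixed other parameters.

    For each value the up/down dose-response is computed; the Gradient and
    the MAPKK-activation signal range — S(0.9 Q_max) - S(0.1 Q_max) for
    Q = free [pp-MAPKK] / [MAPKK]_total, from the beginning to the maximum
    of MAPKK activation — are extracted, and Pearson correlations of both
    against [MAPKK]_total are returned.
    """
    config = config or RunConfig()
    solver = solver or config.solver
    mapkk_values = np.asarray(mapkk_values, dtype=float)
    if len(np.unique(mapkk_values)) < 5:
        raise ValueError("need at least 5 distinct [MAPKK]_total values")
    s_grid = config.s_grid()
    kept_v, kept_g, kept_r = [], [], []
    for v in mapkk_values:
        cv_v = cv.replace_mapkk(float(v))
        dr = dose_response_sweep(network, rates, cv_v, s_grid, solver)
        if dr.o_ss_max <= config.thresholds.responsive_o_max:
            warnings.warn(f"[MAPKK]_total = {v}: non-responsive point dropped")
            continue
        g = gradient(dr, config.thresholds)
        # signal range on the MAPKK tier
        q = np.where(dr.up_mask, dr.up_states[:, _PP_MAPKK] / v, np.nan)
        q_max = np.nanmax(q)
        if q_max <= 0:
            warnings.warn(f"[MAPKK]_total = {v}: no MAPKK activation; dropped")
            continue
        s_lo = _crossing(s_grid, q, 0.1 * q_max)
        s_hi = _crossing(s_grid, q, 0.9 * q_max)
        kept_v.append(v)
        kept_g.append(g.value)
        kept_r.append(s_hi - s_lo)
    if len(kept_v) < 3:
        raise InsufficientDataError(
            f"only {len(kept_v)} responsive scan points; need >= 3")
    kept_v, kept_g, kept_r = map(np.asarray, (kept_v, kept_g, kept_r))
    if np.ptp(kept_g) == 0 or np.ptp(kept_r) == 0:
        raise DegenerateScanError("identical values across scan; "
                                  "correlation undefined")
    return MapkkScanResult(kept_v, kept_g, kept_r,
                           _pearson(kept_v, kept_g), _pearson(kept_v, kept_r))


def _crossing(s: np.ndarray, o: np.ndarray, target: float) -> float:
    """Smallest interpolated stimulus where o crosses target (nan-safe)."""
    m = np.isfinite(o)
    s, o = s[m], o[m]
    if o[0] >= target:
        return float(s[0])
    for i in range(len(o) - 1):
        if (o[i] - target) * (o[i + 1] - target) <= 0 and o[i] != o[i + 1]:
            w = (target - o[i]) / (o[i + 1] - o[i])
            if s[i] > 0:
                return float(np.exp(np.log(s[i])
                                    + w * (np.log(s[i + 1]) - np.log(s[i]))))
            return float(s[i] + w * (s[i + 1] - s[i]))
    return float(s[-1])


def group_by_gradient(reports) -> dict[str, list]:
    """Partition reports into low (1, 10], medium (10, 100], high (100, inf).

    Boundary values go to the lower-open / upper-closed bin (a Gradient of
    exactly 10 is 'low', exactly 100 is 'medium').  Reports with
    Gradient <= 1 or undefined are omitted.
    """
    out: dict[str, list] = {"low": [], "medium": [], "high": []}
    for rep in reports:
        g = rep.gradient if hasattr(rep, "gradient") else rep.get("gradient")
        if g is None or not np.isfinite(g) or g <= 1.0:
            continue
        if g <= 10.0:
            out["low"].append(rep)
        elif g <= 100.0:
            out["medium"].append(rep)
        else:
            out["high"].append(rep)
    return out
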