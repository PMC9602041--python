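"""Experiment orchestration: simulate, window, quantify, and export planes.

One experiment sweeps plasticity mode x damage level on a *shared* topology,
damage and drive stream (paired comparison: mode differences are attributable
to the triplet LTD term alone).  Each simulation's membrane record is cut into
non-overlapping 1000 ms windows of sustained activity; per window and per
rhythm band two global series are built from the band-filtered traces of the
undamaged neurons:

* ``lfp`` — the local field potential, the per-ms sum of all membrane
  potentials;
* ``js_pair`` — the Jensen–Shannon distances between the ordinal PDFs of all
  unordered neuron pairs, in lexicographic pair order.

The ordinal PDF of each global series is then summarized by the (H, F, C)
quantifiers, one CSV row per (mode, damage, band, window, source).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import infoquant, spectral
from .infoquant import OrdinalConfig, QuantifierRecord
from .network import DamageMask, DriveConfig, NetworkConfig, apply_damage, build_topology, simulate
from .plasticity import PlasticityParams
from .spectral import BANDS, bandpass

__all__ = [
    "Seeds",
    "ExperimentConfig",
    "lfp_series",
    "pairwise_js_series",
    "window_quantifiers",
    "select_windows",
    "run_experiment",
    "write_result_table",
    "export_planes",
    "RESULT_COLUMNS",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["mode", "n_damaged", "band", "window_index", "source", "H", "F", "C"]

#: CSV floats carry 17 significant digits so reruns are byte-identical.
FLOAT_FORMAT = "%.17g"


@dataclass(frozen=True)
class Seeds:
    """Named RNG streams; each component of the experiment draws from its own."""

    topology: int = 1
    damage: int = 2
    drive: int = 3


@dataclass(frozen=True)
class ExperimentConfig:
    """Full declarative description of one simulation/analysis sweep."""

    network: NetworkConfig = field(default_factory=NetworkConfig)
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    drive: DriveConfig = field(default_factory=DriveConfig)
    ordinal: OrdinalConfig = field(default_factory=OrdinalConfig)
    seeds: Seeds = field(default_factory=Seeds)
    modes: tuple[str, ...] = ("pairwise", "mixed")
    damage_levels: tuple[int, ...] = (0, 100, 200, 300)
    bands: tuple[str, ...] = tuple(BANDS)
    duration: int = 60_000
    window_len: int = 1000
    n_windows: int = 20
    settle_ms: int = 1000
    min_spikes_per_window: int = 10
    target_band: str | None = None
    sources: tuple[str, ...] = ("lfp", "js_pair")

    def __post_init__(self) -> None:
        for m in self.modes:
            if m not in ("pairwise", "mixed"):
                raise ValueError(f"unknown mode {m!r}")
        for b in self.bands:
            if b not in BANDS:
                raise ValueError(f"unknown band {b!r}")
        for s in self.sources:
            if s not in ("lfp", "js_pair"):
                raise ValueError(f"unknown analysis source {s!r}")
        if self.target_band is not None and self.target_band not in BANDS:
            raise ValueError(f"unknown target band {self.target_band!r}")
        if self.window_len < 1:
            raise ValueError("window_len must be positive")
        if any(lv < 0 or lv > self.network.n_exc for lv in self.damage_levels):
            raise ValueError("damage levels must lie in [0, n_exc]")
        if self.settle_ms + self.window_len > self.duration:
            raise ValueError("duration too short for even one window after settling")


def lfp_series(window: np.ndarray) -> np.ndarray:
    """Local field potential: per-ms sum of the membrane potentials of all
    (undamaged) neurons in a (time x neuron) window."""
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 2 or w.shape[1] == 0:
        raise ValueError("window must be a (time x neuron) matrix with >= 1 neuron")
    return w.sum(axis=1)


def pairwise_js_series(pdfs: np.ndarray) -> np.ndarray:
    """Jensen–Shannon distances between all unordered neuron pairs.

    ``pdfs`` is (K x n_states); the output has length K(K-1)/2, ordered by
    lexicographic pair index (0,1), (0,2), ..., (K-2, K-1).
    """
    p = np.asarray(pdfs, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("need ordinal PDFs for at least 2 neurons")

    def ent_rows(m: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            lo = np.where(m > 0, np.log(m), 0.0)
        return -(m * lo).sum(axis=1)

    s = ent_rows(p)
    blocks = []
    for i in range(p.shape[0] - 1):
        mix = 0.5 * (p[i] + p[i + 1 :])
        div = ent_rows(mix) - 0.5 * (s[i] + s[i + 1 :])
        blocks.append(np.sqrt(np.clip(div, 0.0, None)))
    return np.concatenate(blocks)


def window_quantifiers(
    window: np.ndarray,
    band: str | tuple[float, float] | None,
    ordinal: OrdinalConfig = OrdinalConfig(),
    sources: tuple[str, ...] = ("lfp", "js_pair"),
    fs: float = 1000.0,
) -> dict[str, QuantifierRecord]:
    """Quantify one (time x neuron) membrane window in one rhythm band.

    The traces are band-filtered (zero phase; skipped when ``band`` is None,
    i.e. broadband), then each configured global series is built and its
    ordinal PDF summarized.  Pure: identical windows give identical records.
    """
    w = np.asarray(window, dtype=np.float64)
    if w.ndim != 2:
        raise ValueError("window must be a (time x neuron) matrix")
    filt = w if band is None else bandpass(w, band, fs=fs, axis=0)
    out: dict[str, QuantifierRecord] = {}
    if "lfp" in sources:
        out["lfp"] = infoquant.quantifiers(infoquant.bp_pdf(lfp_series(filt), ordinal))
    if "js_pair" in sources:
        pdfs = np.stack([infoquant.bp_pdf(filt[:, k], ordinal) for k in range(filt.shape[1])])
        series = pairwise_js_series(pdfs)
        out["js_pair"] = infoquant.quantifiers(infoquant.bp_pdf(series, ordinal))
    return out


def select_windows(raster, cfg: ExperimentConfig) -> list[int]:
    """Start times of the first ``n_windows`` usable non-overlapping windows.

    A window is usable when it contains sustained activity (at least
    ``min_spikes_per_window`` population spikes) and, if ``target_band`` is
    set, when the dominant band of its population-rate spectrum matches —
    the oscillation-of-interest stopping rule.
    """
    hist = spectral.spike_histogram(raster, raster.duration)
    starts: list[int] = []
    t = cfg.settle_ms
    while t + cfg.window_len <= raster.duration and len(starts) < cfg.n_windows:
        chunk = hist[t : t + cfg.window_len]
        ok = chunk.sum() >= cfg.min_spikes_per_window
        if ok and cfg.target_band is not None:
            try:
                ok = spectral.band_of_counts(chunk) == cfg.target_band
            except ValueError:
                ok = False
        if ok:
            starts.append(t)
        t += cfg.window_len
    if len(starts) < cfg.n_windows:
        raise ValueError(
            f"only {len(starts)} usable windows found, {cfg.n_windows} requested"
        )
    return starts


def run_experiment(cfg: ExperimentConfig, out_csv: str | Path | None = None) -> pd.DataFrame:
    """Run the full mode x damage sweep and return the result table.

    Topology is drawn once and shared; the damage mask and drive stream are
    drawn per damage level and shared across modes, so the pairwise/mixed
    comparison is paired.  One row per (mode, damage, band, window, source).
    """
    infoquant.verify_reference_example()
    topology = build_topology(cfg.network, np.random.default_rng(cfg.seeds.topology))
    rows: list[tuple] = []
    for n_damaged in cfg.damage_levels:
        dmg = apply_damage(
            cfg.network, n_damaged, np.random.default_rng([cfg.seeds.damage, n_damaged])
        )
        keep = np.flatnonzero(~dmg.as_bool(cfg.network.n_total))
        for mode in cfg.modes:
            pl = replace(cfg.plasticity, mode=mode)
            res = simulate(
                cfg.network,
                cfg.duration,
                plasticity=pl,
                damage=dmg,
                drive=cfg.drive,
                synapses=topology,
                rng_drive=np.random.default_rng([cfg.seeds.drive, n_damaged]),
            )
            starts = select_windows(res.raster, cfg)
            for wi, start in enumerate(starts):
                win = res.v_mv[start : start + cfg.window_len, keep].astype(np.float64)
                for band in cfg.bands:
                    recs = window_quantifiers(win, band, cfg.ordinal, cfg.sources)
                    for source, q in recs.items():
                        rows.append((mode, n_damaged, band, wi, source, q.H, q.F, q.C))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if out_csv is not None:
        write_result_table(table, out_csv)
    return table


def write_result_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def export_planes(
    table: pd.DataFrame,
    out_dir: str | Path,
    bands: tuple[str, ...] | None = None,
    plot: bool = False,
) -> list[Path]:
    """Write per-band H x F, H x C and C x H x F plane tables (values copied,
    never recomputed).  Optionally render scatter plots if matplotlib is
    available."""
    if table.empty:
        raise ValueError("result table is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if bands is None:
        bands = tuple(pd.unique(table["band"]))
    if not bands:
        logger.warning("empty band subset: no plane files written")
        return []
    written: list[Path] = []
    planes = {"HF": ["H", "F"], "HC": ["H", "C"], "HFC": ["H", "F", "C"]}
    meta = ["mode", "n_damaged", "window_index", "source"]
    for band in bands:
        sub = table[table["band"] == band]
        if sub.empty:
            logger.warning("no rows for band %s: skipped", band)
            continue
        for name, cols in planes.items():
            path = out_dir / f"plane_{name}_{band}.csv"
            sub[meta + cols].to_csv(path, index=False, float_format=FLOAT_FORMAT)
            written.append(path)
        if plot:
            _plot_band(sub, band, out_dir)
    return written


def _plot_band(sub: pd.DataFrame, band: str, out_dir: Path) -> None:
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is optional
        logger.warning("matplotlib not installed: skipping plots")
        return
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for mode, marker in (("pairwise", "o"), ("mixed", "^")):
        m = sub[sub["mode"] == mode]
        if m.empty:
            continue
        axes[0].scatter(m["H"], m["F"], c=m["n_damaged"], marker=marker, label=mode, alpha=0.7)
        axes[1].scatter(m["H"], m["C"], c=m["n_damaged"], marker=marker, label=mode, alpha=0.7)
    axes[0].set_xlabel("H"), axes[0].set_ylabel("F")
    axes[1].set_xlabel("H"), axes[1].set_ylabel("C")
    axes[0].legend()
    fig.suptitle(f"{band} band")
    fig.tight_layout()
    fig.savefig(out_dir / f"planes_{band}.png", dpi=120)
    plt.close(fig)
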