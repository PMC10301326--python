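"""CSV readers/writers, run configuration, and the end-to-end pipeline.

Interchange formats (RFC-4180 CSV, UTF-8, ``.`` decimal):

* kinetic curves -- two columns ``time_s,intensity_au`` (bioluminescence) or
  ``time_s,absorbance`` (445/380-nm traces), with a header row;
* viscosity series -- ``eta_cP,k_value,cosolvent,wt_percent``;
* emission spectra -- ``wavelength_nm,intensity_au``.

``run_pipeline`` ties the stages together in the experimental order: estimate
the dark-decay constants from the absorbance traces, fix them in the global
five-curve fit, extract the empirical curve parameters, and (when a viscosity
series is supplied) fit the power law. All artifacts are JSON with
provenance (input hashes, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .reaction_model import KineticCurve
from .fitting import SingleTurnoverDataset, SingleTurnoverModel
from .empirical import empirical_params
from .dark_decay import fit_kd, fit_kdd
from .viscosity import ViscosityPoint, fit_power_law, classify_diffusion_control
from .spectra import EmissionSpectrum

__all__ = [
    "read_curve",
    "write_curve",
    "read_viscosity_series",
    "read_spectrum",
    "RunConfig",
    "run_pipeline",
    "ParseError",
]

_SIGNAL_COLUMNS = {
    "intensity_au": "bioluminescence",
    "absorbance": "absorbance_445",  # refined by config/meta when known
}


class ParseError(ValueError):
    """Malformed input file."""


def read_curve(path, signal_kind: str | None = None, meta: dict | None = None) -> KineticCurve:
    """Read a kinetic curve from a two-column CSV with header ``time_s,<signal>``.

    Malformed rows, a missing/unknown header, and non-monotone timestamps are
    rejected with the offending line number where applicable.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise ParseError(
            f"{path}: expected header 'time_s,<signal>', got {list(df.columns)!r}"
        )
    signal_col = df.columns[1]
    if signal_kind is None:
        signal_kind = _SIGNAL_COLUMNS.get(signal_col, "bioluminescence")
    t = pd.to_numeric(df["time_s"], errors="coerce").to_numpy()
    y = pd.to_numeric(df[signal_col], errors="coerce").to_numpy()
    for arr, name in ((t, "time_s"), (y, signal_col)):
        bad = np.nonzero(~np.isfinite(arr))[0]
        if len(bad):
            # +2: one for the header row, one for 1-based numbering
            raise ParseError(f"{path}: non-numeric {name} value at line {bad[0] + 2}")
    steps = np.diff(t)
    bad = np.nonzero(steps <= 0)[0]
    if len(bad):
        raise ParseError(
            f"{path}: time not strictly increasing at line {bad[0] + 3} "
            f"(t={t[bad[0] + 1]:g} follows t={t[bad[0]]:g})"
        )
    if len(t) < 2:
        raise ParseError(f"{path}: need at least 2 samples, got {len(t)}")
    return KineticCurve(t=t, y=y, signal_kind=signal_kind, meta=dict(meta or {}))


def write_curve(curve: KineticCurve, path) -> None:
    """Write a curve to the two-column CSV dialect ``read_curve`` accepts."""
    col = "absorbance" if curve.signal_kind.startswith("absorbance") else "intensity_au"
    pd.DataFrame({"time_s": curve.t, col: curve.y}).to_csv(path, index=False)


def read_viscosity_series(path) -> list:
    """Read ``eta_cP,k_value[,cosolvent,wt_percent]`` CSV into ViscosityPoints."""
    df = pd.read_csv(path)
    required = {"eta_cP", "k_value"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    points = []
    for i, row in df.iterrows():
        try:
            points.append(
                ViscosityPoint(
                    eta=float(row["eta_cP"]),
                    k=float(row["k_value"]),
                    cosolvent=str(row["cosolvent"]) if "cosolvent" in df.columns else None,
                    wt_percent=float(row["wt_percent"]) if "wt_percent" in df.columns else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: bad viscosity point at line {i + 2}: {exc}") from exc
    return points


def read_spectrum(path, condition: str = "") -> EmissionSpectrum:
    """Read a ``wavelength_nm,intensity_au`` CSV emission spectrum."""
    df = pd.read_csv(path)
    if not {"wavelength_nm", "intensity_au"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns wavelength_nm,intensity_au")
    return EmissionSpectrum(
        lam=df["wavelength_nm"].to_numpy(float),
        intensity=df["intensity_au"].to_numpy(float),
        condition=condition,
    )


@dataclass
class RunConfig:
    """Full-pipeline configuration.

    curve_files: five bioluminescence CSVs, one per decanal concentration
    (decanal_uM in matching order). Concentrations are post-mixing, in uM.
    Either kd/kdd are given directly, or absorbance traces plus windows from
    which to estimate them.
    """

    curve_files: list
    decanal_uM: list
    luciferase_uM: float = 1.0
    fmnh2_uM: float = 15.0
    kd: float | None = None
    kdd: float | None = None
    trace_445: str | None = None
    kd_windows: tuple | None = None  # ((fast_lo, fast_hi), (slow_lo, slow_hi))
    trace_380: str | None = None
    kdd_window: tuple | None = None
    viscosity_series: str | None = None
    n_starts: int = 16
    seed: int = 0
    out_dir: str = "luxkin_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.validate(base=Path(path).parent)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        base = base or Path(".")

        def _resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        if len(self.curve_files) != len(self.decanal_uM):
            raise ValueError("curve_files and decanal_uM must have matching lengths")
        self.curve_files = [str(_resolve(p)) for p in self.curve_files]
        missing = [p for p in self.curve_files if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"curve files not found: {missing}")
        if any(c <= 0 for c in self.decanal_uM) or self.luciferase_uM <= 0 or self.fmnh2_uM <= 0:
            raise ValueError("concentrations must be positive")
        for attr in ("trace_445", "trace_380", "viscosity_series"):
            val = getattr(self, attr)
            if val is not None:
                setattr(self, attr, str(_resolve(val)))
        if self.kd is None and (self.trace_445 is None or self.kd_windows is None):
            raise ValueError("provide either kd or trace_445 + kd_windows")
        if self.kdd is None and (self.trace_380 is None or self.kdd_window is None):
            raise ValueError("provide either kdd or trace_380 + kdd_window")


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    from . import __version__

    files = list(config.curve_files)
    for attr in ("trace_445", "trace_380", "viscosity_series"):
        if getattr(config, attr):
            files.append(getattr(config, attr))
    return {
        "luxkin_version": __version__,
        "seed": config.seed,
        "input_sha256": {str(p): _sha256(p) for p in files},
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis described by a RunConfig.

    Stage order mirrors the experiment: dark-decay estimation (absorbance),
    global five-curve fit with kd/kdd fixed, empirical parameters per curve,
    optional power-law viscosity fit. Writes ``fit.json``, ``empirical.json``,
    ``darkdecay.json``/``powerlaw.json`` when applicable, and ``report.txt``
    to ``config.out_dir``, and returns the report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(config)}

    # stage 1: dark decay
    try:
        kd, kdd = config.kd, config.kdd
        dark = {}
        if kd is None:
            fast, slow = fit_kd(
                read_curve(config.trace_445, signal_kind="absorbance_445"),
                tuple(config.kd_windows[0]),
                tuple(config.kd_windows[1]),
            )
            kd = slow.k
            dark["kd"] = {"fast": vars(fast) | {"window": list(fast.window)},
                          "slow": vars(slow) | {"window": list(slow.window)}}
        if kdd is None:
            fit = fit_kdd(
                read_curve(config.trace_380, signal_kind="absorbance_380"),
                tuple(config.kdd_window),
            )
            kdd = fit.k
            dark["kdd"] = vars(fit) | {"window": list(fit.window)}
        report["dark_decay"] = {"kd": kd, "kdd": kdd, **dark}
        if dark:
            (out / "darkdecay.json").write_text(json.dumps(report["dark_decay"], indent=2))
    except Exception as exc:
        raise RuntimeError(f"[dark_decay] stage failed: {exc}") from exc

    # stage 2: global fit
    try:
        curves = [
            read_curve(p, meta={"A0_M": a * 1e-6, "decanal_uM": a})
            for p, a in zip(config.curve_files, config.decanal_uM)
        ]
        dataset = SingleTurnoverDataset(
            curves=curves,
            L0=config.luciferase_uM * 1e-6,
            F0=config.fmnh2_uM * 1e-6,
            A0_list=[a * 1e-6 for a in config.decanal_uM],
        )
        result = SingleTurnoverModel(dataset, kd=kd, kdd=kdd).fit(
            n_starts=config.n_starts, seed=config.seed
        )
        report["fit"] = result.as_dict()
        (out / "fit.json").write_text(
            json.dumps({**report["fit"], "provenance": report["provenance"]}, indent=2)
        )
    except Exception as exc:
        raise RuntimeError(f"[model_fitting] stage failed: {exc}") from exc

    # stage 3: empirical parameters
    try:
        report["empirical"] = {
            f"{a:g}uM": empirical_params(c).as_dict()
            for c, a in zip(curves, config.decanal_uM)
        }
        (out / "empirical.json").write_text(json.dumps(report["empirical"], indent=2))
    except Exception as exc:
        raise RuntimeError(f"[empirical_kinetics] stage failed: {exc}") from exc

    # stage 4: optional viscosity power law
    if config.viscosity_series:
        try:
            points = read_viscosity_series(config.viscosity_series)
            pl = fit_power_law(points)
            report["powerlaw"] = {
                **vars(pl),
                "regime": classify_diffusion_control(pl),
            }
            (out / "powerlaw.json").write_text(json.dumps(report["powerlaw"], indent=2))
        except Exception as exc:
            raise RuntimeError(f"[viscosity_analysis] stage failed: {exc}") from exc

    lines = [
        "luxkin pipeline report",
        f"kd = {kd:.4g} 1/s, kdd = {kdd:.4g} 1/s "
        + ("(estimated)" if "kd" in report.get("dark_decay", {}) else "(supplied)"),
        "",
        result.summary(),
    ]
    if "powerlaw" in report:
        p = report["powerlaw"]
        lines += [
            "",
            f"power law: A = {p['A']:.4g}, delta = {p['delta']:.3f} "
            f"+/- {p['delta_stderr']:.3f} ({p['regime']})",
        ]
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return report
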