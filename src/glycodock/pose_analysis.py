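"""Pose-consistency analytics: the RMSD triad, torsional deviation profiles,
recapitulation flags and the score/RMSD selectivity parameter.

Docked and native poses live in the common receptor frame, so every RMSD here
is computed in place, without superposition — aligning first would erase
exactly the translational error the triad is meant to expose.  The triad:

* RMSD_AVERAGE — mean native-vs-pose RMSD over the analysis set (by default
  the mean of the per-pose RMSDs; an rmsd-to-centroid mode is available),
* RMSD_LOWEST  — the single best native-vs-pose RMSD,
* RMSD_INTRAPOSE — mean RMSD over all unordered pose pairs (15 for six).

A set recapitulates the native pose when RMSD_AVERAGE <= 2.5 Å and binds
consistently when RMSD_INTRAPOSE <= 2.5 Å; a consistent-but-not-recapitulated
set has converged to a single pose away from the native site.  Torsional
deviations are circular-mean magnitudes |Delta phi|, |Delta psi| in [0, 180]
per linkage.  The selectivity ratio mean_score / RMSD_AVERAGE flags putative
high-affinity, high-selectivity systems (threshold 50 by default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geometry import circular_mean_deg, wrap_angle
from .glycan_core import GagChain, compute_dihedral

__all__ = [
    "AnalysisConfig",
    "PoseSetMetrics",
    "CorrespondenceError",
    "pose_rmsd",
    "metric_triad",
    "torsion_deviation",
    "selectivity_ratio",
    "compute_metrics",
    "protocol_report",
]


class CorrespondenceError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    rmsd_threshold: float = 2.5  # Å, geometric-equivalence cut-off
    ratio_threshold: float = 50.0  # score/RMSD selectivity cut-off
    rmsd_mode: str = "mean-of-rmsds"  # or "rmsd-to-centroid"
    symmetry_handling: bool = False
    length_scaled_threshold: bool = False  # optional per-length scaling hook
    length_scale_ref: int = 4  # residues at which the threshold applies as-is

    def __post_init__(self):
        if self.rmsd_threshold <= 0 or self.ratio_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.rmsd_mode not in ("mean-of-rmsds", "rmsd-to-centroid"):
            raise ValueError(f"unknown rmsd_mode {self.rmsd_mode!r}")

    def threshold_for(self, n_residues: int | None) -> float:
        if not self.length_scaled_threshold or n_residues is None:
            return self.rmsd_threshold
        return self.rmsd_threshold * np.sqrt(n_residues / self.length_scale_ref)


@dataclass
class PoseSetMetrics:
    rmsd_average: float
    rmsd_lowest: float
    rmsd_intrapose: float | None
    per_linkage_dphi: dict
    per_linkage_dpsi: dict
    mean_dphi: float
    mean_dpsi: float
    mean_score: float | None
    selectivity_ratio: float | None
    recapitulated: bool
    consistent: bool | None
    selective: bool | None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["per_linkage_dphi"] = {k: float(v) for k, v in self.per_linkage_dphi.items()}
        d["per_linkage_dpsi"] = {k: float(v) for k, v in self.per_linkage_dpsi.items()}
        return d


# ---------------------------------------------------------------------------
# RMSD


def _equivalent_oxygen_groups(chain: GagChain) -> list[list[int]]:
    """Atom-id groups of chemically equivalent terminal oxygens (the three
    oxygens of each sulfate, the two of each carboxylate)."""
    groups = []
    for res in chain.residues:
        by_name = {chain.atoms[a].name: a for a in res.atom_ids}
        for prefix in ("O6S", "O3S", "O2S", "ONS"):
            g = [by_name[f"{prefix}{k}"] for k in (1, 2, 3) if f"{prefix}{k}" in by_name]
            if len(g) == 3:
                groups.append(g)
        g = [by_name[n] for n in ("O6A", "O6B") if n in by_name]
        if len(g) == 2:
            groups.append(g)
    return groups


def pose_rmsd(a, b, chain: GagChain | None = None, symmetry_handling: bool = False) -> float:
    """In-place heavy-atom RMSD between two poses of the same ligand.

    With symmetry handling on, equivalent terminal oxygens within each
    sulfate/carboxylate group of `b` are permuted to minimize the RMSD;
    groups are disjoint, so each is minimized independently.
    """
    ca = np.asarray(getattr(a, "coords", a), dtype=float)
    cb = np.asarray(getattr(b, "coords", b), dtype=float)
    if ca.shape != cb.shape:
        raise CorrespondenceError(f"atom-count mismatch: {ca.shape} vs {cb.shape}")
    sq = ((ca - cb) ** 2).sum(axis=1)
    if not symmetry_handling or chain is None:
        return float(np.sqrt(sq.mean()))
    total = sq.sum()
    for group in _equivalent_oxygen_groups(chain):
        base = sq[group].sum()
        best = base
        for perm in itertools.permutations(group):
            alt = sum(((ca[i] - cb[j]) ** 2).sum() for i, j in zip(group, perm))
            best = min(best, alt)
        total += best - base
    return float(np.sqrt(total / ca.shape[0]))


def metric_triad(native, poses, cfg: AnalysisConfig = AnalysisConfig(),
                 chain: GagChain | None = None):
    """(rmsd_average, rmsd_lowest, rmsd_intrapose) plus classification flags.

    rmsd_intrapose is reported as None (not 0) for a single pose.  Returns a
    dict with keys rmsd_average, rmsd_lowest, rmsd_intrapose, recapitulated,
    consistent.
    """
    pose_list = list(poses)
    if not pose_list:
        raise ValueError("empty pose set")
    sym = cfg.symmetry_handling
    rmsds = [pose_rmsd(native, p, chain, sym) for p in pose_list]
    if cfg.rmsd_mode == "rmsd-to-centroid":
        centroid = np.mean([np.asarray(getattr(p, "coords", p)) for p in pose_list], axis=0)
        rmsd_average = pose_rmsd(native, centroid, chain, sym)
    else:
        rmsd_average = float(np.mean(rmsds))
    rmsd_lowest = float(np.min(rmsds))
    if len(pose_list) >= 2:
        pair_rmsds = [
            pose_rmsd(p, q, chain, sym) for p, q in itertools.combinations(pose_list, 2)
        ]
        rmsd_intrapose = float(np.mean(pair_rmsds))
    else:
        rmsd_intrapose = None
    thr = cfg.threshold_for(chain.n_residues if chain is not None else None)
    return {
        "rmsd_average": rmsd_average,
        "rmsd_lowest": rmsd_lowest,
        "rmsd_intrapose": rmsd_intrapose,
        "recapitulated": rmsd_average <= thr,
        "consistent": None if rmsd_intrapose is None else rmsd_intrapose <= thr,
    }


# ---------------------------------------------------------------------------
# torsional deviation


def torsion_deviation(native, poses, chain: GagChain):
    """Per-linkage |Delta phi|, |Delta psi| between the native pose and the
    circular mean of the docked poses, plus across-linkage means.

    Deviations are magnitudes in [0, 180]; circular means keep values that
    straddle +/-180 from exploding.
    """
    nat = np.asarray(getattr(native, "coords", native), dtype=float)
    pose_coords = [np.asarray(getattr(p, "coords", p), dtype=float) for p in poses]
    per_phi, per_psi = {}, {}
    for lk in chain.linkages:
        i1, i2, i3, i4 = lk.phi_atoms
        j1, j2, j3, j4 = lk.psi_atoms
        nat_phi = compute_dihedral(nat[i1], nat[i2], nat[i3], nat[i4])
        nat_psi = compute_dihedral(nat[j1], nat[j2], nat[j3], nat[j4])
        phis = [compute_dihedral(c[i1], c[i2], c[i3], c[i4]) for c in pose_coords]
        psis = [compute_dihedral(c[j1], c[j2], c[j3], c[j4]) for c in pose_coords]
        per_phi[lk.label] = abs(wrap_angle(circular_mean_deg(phis) - nat_phi))
        per_psi[lk.label] = abs(wrap_angle(circular_mean_deg(psis) - nat_psi))
    mean_dphi = float(np.mean(list(per_phi.values()))) if per_phi else 0.0
    mean_dpsi = float(np.mean(list(per_psi.values()))) if per_psi else 0.0
    return {
        "per_linkage_dphi": per_phi,
        "per_linkage_dpsi": per_psi,
        "mean_dphi": mean_dphi,
        "mean_dpsi": mean_dpsi,
    }


# ---------------------------------------------------------------------------
# selectivity


def selectivity_ratio(mean_score: float, rmsd_average: float,
                      cfg: AnalysisConfig = AnalysisConfig()):
    """(ratio, selective flag); ratio = mean_score / rmsd_average.

    A zero RMSD yields +inf (selective); a negative mean score computes the
    ratio but forces selective = False with a warning.
    """
    if rmsd_average < 0:
        raise ValueError("rmsd_average must be >= 0")
    if rmsd_average == 0:
        return float("inf"), True
    ratio = mean_score / rmsd_average
    if mean_score < 0:
        warnings.warn("negative mean score; selectivity flag forced False")
        return float(ratio), False
    return float(ratio), bool(ratio >= cfg.ratio_threshold)


def compute_metrics(native, pose_set, chain: GagChain,
                    cfg: AnalysisConfig = AnalysisConfig()) -> PoseSetMetrics:
    """Full PoseSetMetrics for one analysis pose set."""
    triad = metric_triad(native, pose_set, cfg, chain)
    tors = torsion_deviation(native, pose_set, chain)
    scores = [p.score.total for p in pose_set if getattr(p, "score", None) is not None]
    mean_score = float(np.mean(scores)) if scores else None
    if mean_score is not None:
        ratio, selective = selectivity_ratio(mean_score, triad["rmsd_average"], cfg)
    else:
        ratio, selective = None, None
    return PoseSetMetrics(
        rmsd_average=triad["rmsd_average"],
        rmsd_lowest=triad["rmsd_lowest"],
        rmsd_intrapose=triad["rmsd_intrapose"],
        per_linkage_dphi=tors["per_linkage_dphi"],
        per_linkage_dpsi=tors["per_linkage_dpsi"],
        mean_dphi=tors["mean_dphi"],
        mean_dpsi=tors["mean_dpsi"],
        mean_score=mean_score,
        selectivity_ratio=ratio,
        recapitulated=triad["recapitulated"],
        consistent=triad["consistent"],
        selective=selective,
    )


# ---------------------------------------------------------------------------
# consolidated reporting


def protocol_report(systems, cfg: AnalysisConfig = AnalysisConfig(), out_dir=None):
    """Per-system, per-protocol metric table plus stratified recapitulation
    fractions and figure-style bar plots.

    `systems` is a list of dicts with keys: name, chain, native and
    pose_sets (mapping regime -> iterable of poses).  Returns (DataFrame,
    summary dict); when out_dir is given, CSV/JSON tables and one bar-plot
    image per metric are written there.
    """
    rows = []
    for system in systems:
        chain = system["chain"]
        native = system["native"]
        for regime, poses in system["pose_sets"].items():
            m = compute_metrics(native, poses, chain, cfg)
            rows.append(
                {
                    "system": system["name"],
                    "length": chain.n_residues,
                    "regime": regime,
                    "rmsd_average": m.rmsd_average,
                    "rmsd_lowest": m.rmsd_lowest,
                    "rmsd_intrapose": m.rmsd_intrapose,
                    "mean_dphi": m.mean_dphi,
                    "mean_dpsi": m.mean_dpsi,
                    "mean_score": m.mean_score,
                    "selectivity_ratio": m.selectivity_ratio,
                    "recapitulated": m.recapitulated,
                    "consistent": m.consistent,
                    "selective": m.selective,
                }
            )
    df = pd.DataFrame(rows)
    summary: dict = {"rmsd_threshold": cfg.rmsd_threshold, "ratio_threshold": cfg.ratio_threshold}
    if not df.empty:
        frac = df.groupby("regime")["recapitulated"].mean().to_dict()
        summary["recapitulation_fraction"] = frac
        short = df[df["length"] <= 4]
        long_ = df[df["length"] >= 5]
        summary["recapitulation_fraction_2_4mer"] = (
            short.groupby("regime")["recapitulated"].mean().to_dict()
        )
        summary["recapitulation_fraction_5_10mer"] = (
            long_.groupby("regime")["recapitulated"].mean().to_dict()
        )
        summary["mean_dpsi_by_regime"] = df.groupby("regime")["mean_dpsi"].mean().to_dict()
        summary["mean_dphi_by_regime"] = df.groupby("regime")["mean_dphi"].mean().to_dict()
    if out_dir is not None:
        _write_report(df, summary, cfg, out_dir)
    return df, summary


def _write_report(df: pd.DataFrame, summary: dict, cfg: AnalysisConfig, out_dir) -> None:
    import json
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "metrics.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    if df.empty:
        return
    for metric in ("rmsd_average", "rmsd_lowest", "rmsd_intrapose"):
        fig, ax = plt.subplots(figsize=(8, 4))
        piv = df.pivot_table(index="system", columns="regime", values=metric)
        piv.plot.bar(ax=ax)
        ax.axhline(cfg.rmsd_threshold, color="red", linestyle=":", label="threshold")
        ax.set_ylabel(f"{metric} (Å)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"{metric}.png", dpi=100)
        plt.close(fig)
    fig, ax = plt.subplots(figsize=(8, 4))
    piv = df.pivot_table(index="system", columns="regime", values="selectivity_ratio")
    piv.plot.bar(ax=ax)
    ax.axhline(cfg.ratio_threshold, color="black", linestyle=":", label="ratio threshold")
    ax.set_ylabel("mean score / RMSD_AVERAGE")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "selectivity_ratio.png", dpi=100)
    plt.close(fig)
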