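"""Glycosidic-torsion curation and bounded torsional probability histograms.

Crystallographic surveys of Hp/HS-protein complexes show the glycosidic
Phi/Psi pairs clustering in a narrow +/-30 deg band around a small number of
minima: two for the UA->GlcN linkage class (~(-80,-100) and ~(-80,65)) and
one for GlcN->UA (~(80,-145)).  The semi-rigid docking regime exploits this
by sampling each glycosidic torsion from a bell-shaped histogram bounded
around a chosen center instead of the full circle.

The distribution-file format is this package's own documented text format
(one header, one "angle weight" line per bin); no attempt is made to mimic
any proprietary dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import circular_mean_deg, circular_std_deg, wrap_angle
from .glycan_core import GagChain

__all__ = [
    "TorsionObservation",
    "TorsionHistogram",
    "TorsionMixture",
    "DistributionFileError",
    "build_histogram",
    "sample_torsion",
    "curate_torsions",
    "write_distribution_file",
    "read_distribution_file",
    "default_class_histograms",
    "observations_to_csv",
    "ramachandran_plot",
]


class DistributionFileError(ValueError):
    pass


@dataclass
class TorsionObservation:
    source_id: str
    linkage_class: str
    phi: float
    psi: float


@dataclass
class TorsionHistogram:
    """Normalized probability weights over 1-degree-ish bins of (-180, 180],
    zero outside a circular window [center - halfwidth, center + halfwidth]."""

    center: float
    halfwidth: float
    bin_width: float
    weights: np.ndarray
    shape: str = "raised-cosine"

    @property
    def n_bins(self) -> int:
        return self.weights.size

    @property
    def midpoints(self) -> np.ndarray:
        return -180.0 + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def supports(self, angle: float) -> bool:
        return abs(wrap_angle(angle - self.center)) <= self.halfwidth + 1e-9

    def sample(self, rng: np.random.Generator) -> float:
        """Inverse-CDF draw (bin by weight, uniform within the bin), clipped
        to the circular support."""
        idx = rng.choice(self.n_bins, p=self.weights)
        val = self.midpoints[idx] + rng.uniform(-self.bin_width / 2.0, self.bin_width / 2.0)
        delta = np.clip(wrap_angle(val - self.center), -self.halfwidth, self.halfwidth)
        return wrap_angle(self.center + delta)

    def validate(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("histogram weights must sum to 1")
        delta = np.abs(wrap_angle(self.midpoints - self.center))
        if np.any(self.weights[delta > self.halfwidth + self.bin_width / 2 + 1e-9] > 0):
            raise ValueError("nonzero weight outside the histogram support")


@dataclass
class TorsionMixture:
    """Equal-weight (by default) mixture of bounded histograms, used for the
    bimodal UA->GlcN class."""

    components: list
    mixture_weights: list | None = None

    def sample(self, rng: np.random.Generator) -> float:
        w = self.mixture_weights
        if w is None:
            w = [1.0 / len(self.components)] * len(self.components)
        k = rng.choice(len(self.components), p=np.asarray(w) / np.sum(w))
        return self.components[k].sample(rng)

    def supports(self, angle: float) -> bool:
        return any(c.supports(angle) for c in self.components)


def build_histogram(
    center: float,
    halfwidth: float = 30.0,
    bin_width: float = 1.0,
    shape: str = "raised-cosine",
) -> TorsionHistogram:
    """Bell-shaped bounded histogram, symmetric about `center`.

    Shapes: "raised-cosine" (weight ~ cos^2(pi*delta / (2*halfwidth)), exactly
    zero outside the window), "truncated-gaussian" (sd = halfwidth/2) and
    "flat" (the flexible regime's implicit prior when halfwidth = 180).
    """
    if not 0.0 < halfwidth <= 180.0:
        raise ValueError("halfwidth must be in (0, 180]")
    if bin_width <= 0 or abs(360.0 / bin_width - round(360.0 / bin_width)) > 1e-9:
        raise ValueError("bin_width must divide 360")
    n = int(round(360.0 / bin_width))
    mids = -180.0 + (np.arange(n) + 0.5) * bin_width
    delta = np.abs(wrap_angle(mids - center))
    inside = delta <= halfwidth
    if shape == "raised-cosine":
        w = np.where(inside, np.cos(np.pi * delta / (2.0 * halfwidth)) ** 2, 0.0)
    elif shape == "truncated-gaussian":
        sd = halfwidth / 2.0
        w = np.where(inside, np.exp(-0.5 * (delta / sd) ** 2), 0.0)
    elif shape == "flat":
        w = inside.astype(float)
    else:
        raise ValueError(f"unknown histogram shape {shape!r}")
    if w.sum() <= 0:  # halfwidth narrower than half a bin: all mass at center
        w = np.zeros(n)
        w[int(np.argmin(np.abs(wrap_angle(mids - center))))] = 1.0
    w = w / w.sum()
    return TorsionHistogram(float(center), float(halfwidth), float(bin_width), w, shape)


def sample_torsion(hist, rng: np.random.Generator) -> float:
    """Draw one torsion (degrees) from a histogram or mixture."""
    return hist.sample(rng)


def default_class_histograms(halfwidth: float = 30.0, bin_width: float = 1.0):
    """Literature-minima defaults per linkage class: a bimodal equal-weight
    mixture for UA->GlcN and a single bell for GlcN->UA, for Phi and Psi."""
    from .fixtures import DEFAULT_CLASS_CENTERS

    out = {}
    for link_class, modes in DEFAULT_CLASS_CENTERS.items():
        phi_parts = [build_histogram(m[0], halfwidth, bin_width) for m in modes]
        psi_parts = [build_histogram(m[1], halfwidth, bin_width) for m in modes]
        out[link_class] = {
            "phi": phi_parts[0] if len(phi_parts) == 1 else TorsionMixture(phi_parts),
            "psi": psi_parts[0] if len(psi_parts) == 1 else TorsionMixture(psi_parts),
        }
    return out


# ---------------------------------------------------------------------------
# curation


def curate_torsions(chains, source_ids=None):
    """Extract one (Phi, Psi) observation per glycosidic linkage and summarize
    per linkage class.

    Returns (observations, summary) where summary maps linkage class to
    circular means/SDs and kernel-density modes (candidate histogram centers;
    reported, not asserted).
    """
    if source_ids is None:
        source_ids = [f"chain{k}" for k in range(len(chains))]
    obs: list[TorsionObservation] = []
    for chain, sid in zip(chains, source_ids):
        for lk in chain.linkages:
            obs.append(TorsionObservation(sid, lk.linkage_class, lk.phi, lk.psi))
    summary = {}
    for link_class in sorted({o.linkage_class for o in obs}):
        phis = np.array([o.phi for o in obs if o.linkage_class == link_class])
        psis = np.array([o.psi for o in obs if o.linkage_class == link_class])
        summary[link_class] = {
            "n": phis.size,
            "phi_mean": circular_mean_deg(phis),
            "psi_mean": circular_mean_deg(psis),
            "phi_std": circular_std_deg(phis),
            "psi_std": circular_std_deg(psis),
            "kde_modes": _kde_modes_2d(phis, psis),
        }
    return obs, summary


def _kde_modes_2d(phis, psis, grid_step: float = 2.0, bandwidth_deg: float = 15.0,
                  rel_threshold: float = 0.25, max_modes: int = 4):
    """Local maxima of a product von-Mises KDE on the (Phi, Psi) torus."""
    if phis.size == 0:
        return []
    kappa = 1.0 / np.radians(bandwidth_deg) ** 2
    grid = np.arange(-180.0 + grid_step / 2.0, 180.0, grid_step)
    gp = np.radians(grid)
    op, os_ = np.radians(phis), np.radians(psis)
    # separable accumulation over observations
    dens = np.zeros((grid.size, grid.size))
    for p, s in zip(op, os_):
        dens += np.exp(kappa * (np.cos(gp - p)[:, None] + np.cos(gp - s)[None, :] - 2.0))
    peak = dens.max()
    modes = []
    for i in range(grid.size):
        for j in range(grid.size):
            v = dens[i, j]
            if v < rel_threshold * peak:
                continue
            neigh = [
                dens[(i + di) % grid.size, (j + dj) % grid.size]
                for di in (-1, 0, 1)
                for dj in (-1, 0, 1)
                if (di, dj) != (0, 0)
            ]
            if v > max(neigh):
                modes.append((float(grid[i]), float(grid[j]), float(v)))
    modes.sort(key=lambda m: -m[2])
    return [(m[0], m[1]) for m in modes[:max_modes]]


def observations_to_csv(observations, path) -> None:
    """Write a TorsionObservation table as CSV (source_id, class, phi, psi)."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "source_id": o.source_id,
                "linkage_class": o.linkage_class,
                "phi": o.phi,
                "psi": o.psi,
            }
            for o in observations
        ]
    ).to_csv(path, index=False)


def ramachandran_plot(observations, path, title: str = "glycosidic torsions") -> None:
    """Phi/Psi scatter over (-180, 180]^2, one color per linkage class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    classes = sorted({o.linkage_class for o in observations})
    for link_class in classes:
        phis = [o.phi for o in observations if o.linkage_class == link_class]
        psis = [o.psi for o in observations if o.linkage_class == link_class]
        ax.scatter(phis, psis, s=12, alpha=0.7, label=link_class)
    ax.set_xlim(-180, 180)
    ax.set_ylim(-180, 180)
    ax.set_xlabel("Phi (deg)")
    ax.set_ylabel("Psi (deg)")
    ax.set_title(title)
    if classes:
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# distribution files


def write_distribution_file(hist: TorsionHistogram, linkage_id: str, path) -> None:
    """Plain-text distribution: header (linkage id, center, halfwidth,
    bin width, shape) then one "angle weight" line per bin; weights kept at
    full precision so a round-trip is exact."""
    with open(path, "w") as fh:
        fh.write("# glycodock torsion-distribution v1\n")
        fh.write(f"linkage {linkage_id}\n")
        fh.write(
            f"center {float(hist.center)!r} halfwidth {float(hist.halfwidth)!r} "
            f"bin_width {float(hist.bin_width)!r} shape {hist.shape}\n"
        )
        for mid, w in zip(hist.midpoints, hist.weights):
            fh.write(f"{float(mid)!r} {float(w)!r}\n")


def read_distribution_file(path) -> tuple[str, TorsionHistogram]:
    """Inverse of write_distribution_file; rejects non-normalized files."""
    linkage_id = None
    header = {}
    angles, weights = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if parts[0] == "linkage":
                    linkage_id = " ".join(parts[1:])
                elif parts[0] == "center":
                    header = {
                        "center": float(parts[1]),
                        "halfwidth": float(parts[3]),
                        "bin_width": float(parts[5]),
                        "shape": parts[7],
                    }
                else:
                    angles.append(float(parts[0]))
                    weights.append(float(parts[1]))
            except (IndexError, ValueError):
                raise DistributionFileError(f"{path}:{ln}: malformed line {line!r}") from None
    if linkage_id is None or not header or not weights:
        raise DistributionFileError(f"{path}: incomplete distribution file")
    w = np.array(weights)
    if abs(w.sum() - 1.0) > 1e-6:
        raise DistributionFileError(f"{path}: weights sum to {w.sum()!r}, not 1")
    hist = TorsionHistogram(
        header["center"], header["halfwidth"], header["bin_width"], w, header["shape"]
    )
    expected = hist.midpoints
    if len(angles) != expected.size or np.abs(np.array(angles) - expected).max() > 1e-9:
        raise DistributionFileError(f"{path}: bin grid inconsistent with header")
    return linkage_id, hist
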