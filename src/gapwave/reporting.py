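"""Pipeline composition, run configuration, and figure/table export.

`run_full_pipeline` wires the stages in order -- build the network, expand it
into the scattering circuit, solve the spectrum over the energy grid, apply
the conservation post-correction, derive the analysis products (mean curve,
mobility edge, transmission maps, appearance-rate hubs) and the
effective-conductance baseline -- and writes every artifact as CSV/JSON plus
an npz spectrum cache, all stamped with a hash of the configuration for
provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import circuit_model, conductance, network_io, scattering, wdtm_analysis

__all__ = ["RunConfig", "run_full_pipeline", "export_heatmap"]


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run.

    Exactly one of ``network_path`` (CSV edge list) or ``synthetic``
    (generator kind + params) selects the input network.
    """

    network_path: str | None = None
    synthetic: dict | None = None
    cell_types_path: str | None = None
    seed: int = 0
    gamma: float = 5.0
    e_min: float = -10.0
    e_max: float = 10.0
    de: float = 0.025
    conservation_tolerance: float = 1e-5
    band_edge_policy: str = "zero"
    cutoff: float = 0.5
    mobility_threshold: float = 1e-7
    hub_threshold: float = 3.0 / 31.0
    method: str = "fast"
    outdir: str = "gapwave_out"
    heatmaps: bool = False

    def validate(self) -> None:
        if (self.network_path is None) == (self.synthetic is None):
            raise ValueError("config: specify exactly one of network_path or synthetic")
        if self.e_min >= self.e_max or self.de <= 0:
            raise ValueError("config: invalid energy grid")
        if not 2 * self.gamma >= max(abs(self.e_min), abs(self.e_max)):
            raise ValueError("config: energy grid exceeds the band [-2*gamma, 2*gamma]")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _load_network(cfg: RunConfig) -> network_io.GapJunctionNetwork:
    if cfg.network_path is not None:
        net = network_io.read_edge_list(cfg.network_path)
    else:
        params = dict(cfg.synthetic)
        kind = params.pop("kind")
        net = network_io.generate_synthetic(kind, seed=cfg.seed, **params)
    if cfg.cell_types_path:
        net = net.with_cell_types(network_io.read_cell_types(cfg.cell_types_path))
    return net


def run_full_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the artifact bundle; returns the manifest.

    Stage failures raise with the failing stage named, so configuration
    errors surface before any expensive computation starts.
    """
    stage = "validation"
    try:
        cfg.validate()
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        h = cfg.hash()

        stage = "network"
        net = _load_network(cfg)
        network_io.write_edge_list(net, outdir / "network.csv")

        stage = "circuit"
        circuit = circuit_model.build_circuit(net)

        stage = "transmission"
        scfg = scattering.ScatteringConfig(
            gamma=cfg.gamma, conservation_tolerance=cfg.conservation_tolerance,
            band_edge_policy=cfg.band_edge_policy)
        grid = scattering.make_energy_grid(cfg.e_min, cfg.e_max, cfg.de, scfg)
        solver = scattering.TransmissionSolver(circuit, scfg)
        spectrum = solver.spectrum(grid, method=cfg.method)
        spectrum, conservation_report = scattering.conservation_policy(spectrum)
        spectrum.save_npz(outdir / "spectrum.npz", config_hash=h)

        stage = "analysis"
        curve = wdtm_analysis.average_transmission(spectrum)
        pd.DataFrame({"E": curve.E_grid, "mean_T": curve.mean_T}).to_csv(
            outdir / "curve.csv", index=False)
        edge = wdtm_analysis.find_mobility_edge(curve, cfg.mobility_threshold)
        energies = wdtm_analysis.select_wdtm_energies(curve, spectrum, cfg.cutoff)
        names = net.names
        rows = []
        for E in energies:
            wdtm = wdtm_analysis.strong_pairs(spectrum, E, cfg.cutoff)
            for (i, j) in wdtm.pairs:
                rows.append({"E": E, "cell_a": names[i], "cell_b": names[j],
                             "T": wdtm.T[(i, j)]})
        pd.DataFrame(rows, columns=["E", "cell_a", "cell_b", "T"]).to_csv(
            outdir / "wdtm.csv", index=False)
        hubs: list[dict] = []
        if energies:
            rates = wdtm_analysis.appearance_rate(spectrum, energies, cfg.cutoff)
            keep = rates.rate > 0
            pd.DataFrame({
                "cell_a": [names[i] for i in rates.pair_i[keep]],
                "cell_b": [names[j] for j in rates.pair_j[keep]],
                "rate": rates.rate[keep],
            }).to_csv(outdir / "appearance_rates.csv", index=False)
            hubs = wdtm_analysis.find_hubs(rates, cfg.hub_threshold, names)
            pd.DataFrame(hubs, columns=["cell_a", "cell_b", "name_a", "name_b", "rate"]
                         ).to_csv(outdir / "hubs.csv", index=False)

        stage = "conductance"
        gmat = conductance.all_pairs_conductance(net)
        gmat.to_dataframe().to_csv(outdir / "conductance.csv")

        if cfg.heatmaps:
            stage = "figures"
            export_heatmap(spectrum.matrix_at(float(grid[len(grid) // 2])), names,
                           outdir / "transmission_mid.png", log=True)
            export_heatmap(gmat.G, names, outdir / "conductance.png", log=True)

        stage = "manifest"
        manifest = {
            "config": cfg.to_dict(),
            "config_hash": h,
            "n_cells": net.n_cells,
            "n_edges": net.n_edges,
            "n_pairs": spectrum.n_pairs,
            "hamiltonian_dim": circuit.n_nodes,
            "n_grid": int(grid.size),
            "conservation": conservation_report,
            "mobility_edge": list(edge) if edge else None,
            "selected_energies": energies,
            "n_hubs": len(hubs),
            "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()
                                and p.name != "manifest.json"),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err


def export_heatmap(matrix: np.ndarray, labels, path, log: bool = False,
                   eps: float = 1e-12, type_bands=None, title: str | None = None) -> None:
    """Render a square cell-by-cell matrix as a PNG heatmap.

    Cells appear in source order on both axes.  ``log=True`` plots
    ``log10(max(value, eps))``; ``type_bands`` (optional name -> cell_type
    mapping aligned with ``labels``) draws coloured class bands along the
    axes instead of the full 469 tick labels.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("heatmap needs a square matrix")
    if len(labels) != matrix.shape[0]:
        raise ValueError(f"{len(labels)} labels for a {matrix.shape[0]}-row matrix")
    shown = np.log10(np.maximum(matrix, eps)) if log else matrix
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(shown, origin="upper", interpolation="nearest", cmap="viridis")
    fig.colorbar(im, ax=ax, label="log10 value" if log else "value")
    if len(labels) <= 30:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
        ax.set_yticks(range(len(labels)), labels, fontsize=6)
    if type_bands is not None:
        types = [type_bands.get(l, "unknown") for l in labels]
        uniq = sorted(set(types))
        cmap = plt.get_cmap("tab10")
        colors = {t: cmap(i % 10) for i, t in enumerate(uniq)}
        for pos, t in enumerate(types):
            ax.plot([-1.5, -1.5], [pos - 0.5, pos + 0.5], color=colors[t], lw=3,
                    clip_on=False)
        ax.set_xlim(-2.5, len(labels) - 0.5)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
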