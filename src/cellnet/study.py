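"""Experiment drivers: virtual-TFM replication study and sensitivity runs.

`replicate_tfm_study` reproduces the headline experiment: n cells are
generated as statistical realisations of a HUVEC, each is coupled to
the substrate for both load cases (0% and 10% substrate area strain,
10 coupling iterations), the virtual TFM pipeline is applied, and the
per-cell Delta eps_A values and coupling residual histories are
tabulated.

`sensitivity_study` re-runs the same cells under one-at-a-time
parameter variants of the cortex and ventral stress fibres: stiffness
up 30%, activation shortening up 30% (i.e. the activation value is
lowered), and probabilistic per-bond stiffness draws with a 30%
coefficient of variation (negative draws are set to zero).
"""

from __future__ import annotations

import dataclasses
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coupling import CoupledResult, CouplingOptions, run_coupled_equilibrium
from .materials import BondMaterial, DEFAULT_MATERIALS, FibreClass
from .netgen import CellGenParams, CellNetwork, generate_cell, replace_fields
from .substrate import LoadCase, SubstrateSpec
from .tfm import Region, analyse_coupled_result


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of the virtual TFM replication study."""

    n_cells: int = 5
    load_cases: tuple[float, ...] = (0.0, 0.10)
    cell_params: CellGenParams = field(default_factory=CellGenParams)
    substrate: SubstrateSpec = field(default_factory=SubstrateSpec)
    coupling: CouplingOptions = field(default_factory=CouplingOptions)
    n_markers: int = 1500
    imaged_window: float = 200.0  # μm
    seed: int = 0
    output_dir: str | None = None


@dataclass
class CellCaseRecord:
    """One (cell, load case) outcome."""

    cell: int
    area_strain: float
    delta_eps_A: float  # dimensionless
    rbar_initial: float
    rbar_final: float
    rbar_history: list[float]
    coupled: CoupledResult | None = None

    @property
    def reduction_percent(self) -> float:
        return 100.0 * self.rbar_final / self.rbar_initial


@dataclass
class StudyResult:
    """Tabulated outcome of a study run."""

    records: list[CellCaseRecord]
    config: StudyConfig
    label: str = "control"

    def delta_table(self) -> pd.DataFrame:
        """Per-cell Delta eps_A in %, one column per load case, plus the
        cohort mean."""
        df = pd.DataFrame(
            {
                "cell": [r.cell for r in self.records],
                "case": [r.area_strain for r in self.records],
                "delta_pct": [100.0 * r.delta_eps_A for r in self.records],
            }
        )
        wide = df.pivot(index="cell", columns="case", values="delta_pct")
        wide.loc["mean"] = wide.mean()
        return wide

    def residual_table(self) -> pd.DataFrame:
        """Per-cell final Rbar_cell (nN) and final/initial ratio (%)."""
        return pd.DataFrame(
            {
                "cell": [r.cell for r in self.records],
                "case": [r.area_strain for r in self.records],
                "rbar_final_nN": [r.rbar_final for r in self.records],
                "reduction_pct": [r.reduction_percent for r in self.records],
            }
        )

    def mean_delta(self, area_strain: float) -> float:
        vals = [
            r.delta_eps_A for r in self.records if r.area_strain == area_strain
        ]
        return float(np.mean(vals))

    def mean_reduction(self, area_strain: float) -> float:
        vals = [
            r.reduction_percent
            for r in self.records
            if r.area_strain == area_strain
        ]
        return float(np.mean(vals))


def centre_network(net: CellNetwork) -> CellNetwork:
    """Shift node coordinates so the cell polygon centroid sits at the
    substrate-domain centre (the origin)."""
    from shapely.geometry import Polygon

    c = np.asarray(Polygon(net.geometry.polygon).centroid.coords[0])
    geo = net.geometry
    geometry = dataclasses.replace(
        geo,
        polygon=geo.polygon - c,
        membrane_points=geo.membrane_points - c,
        nucleus=dataclasses.replace(
            geo.nucleus, centre=tuple(np.asarray(geo.nucleus.centre) - c)
        ),
        nuclear_membrane_points=geo.nuclear_membrane_points - c,
    )
    return replace_fields(net, positions=net.positions - c, geometry=geometry)


def generate_cohort(config: StudyConfig) -> list[CellNetwork]:
    """Generate ``n_cells`` statistically independent cells, centred on
    the substrate."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_cells)
    cells = []
    for s in seeds:
        params = dataclasses.replace(config.cell_params, seed=int(s % 2**31))
        cells.append(centre_network(generate_cell(params)))
    return cells


def run_cell_case(
    net: CellNetwork,
    area_strain: float,
    config: StudyConfig,
    cell_index: int = 0,
    rng: np.random.Generator | None = None,
    keep_coupled: bool = True,
) -> CellCaseRecord:
    """Couple one cell for one load case and run the TFM pipeline."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    coupled = run_coupled_equilibrium(
        net, config.substrate, LoadCase(area_strain), config.coupling, rng=rng
    )
    tfm_res, _, _, _ = analyse_coupled_result(
        coupled,
        region=Region.centred(config.imaged_window),
        n_markers=config.n_markers,
        seed=rng,
    )
    return CellCaseRecord(
        cell=cell_index,
        area_strain=area_strain,
        delta_eps_A=tfm_res.delta,
        rbar_initial=coupled.rbar_history[0],
        rbar_final=coupled.rbar_history[-1],
        rbar_history=list(coupled.rbar_history),
        coupled=coupled if keep_coupled else None,
    )


def replicate_tfm_study(
    config: StudyConfig = StudyConfig(),
    cells: list[CellNetwork] | None = None,
    keep_coupled: bool = False,
    verbose: bool = False,
) -> StudyResult:
    """Run the full virtual TFM study: generate (or reuse) the cohort,
    couple every cell under every load case, and aggregate."""
    cells = generate_cohort(config) if cells is None else cells
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    records = []
    for i, net in enumerate(cells):
        for eps in config.load_cases:
            t0 = time.time()
            rec = run_cell_case(
                net, eps, config, cell_index=i, rng=rng, keep_coupled=keep_coupled
            )
            records.append(rec)
            if verbose:
                print(
                    f"cell {i} eps_A={eps:.2f}: delta={100 * rec.delta_eps_A:.2f}% "
                    f"reduction={rec.reduction_percent:.1f}% "
                    f"({time.time() - t0:.0f}s)",
                    flush=True,
                )
    result = StudyResult(records=records, config=config)
    if config.output_dir:
        persist_study(result, Path(config.output_dir))
    return result


def persist_study(result: StudyResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.delta_table().to_csv(outdir / f"{result.label}_delta_eps_A.csv")
    result.residual_table().to_csv(
        outdir / f"{result.label}_residuals.csv", index=False
    )
    hist = {
        f"cell{r.cell}_eps{r.area_strain}": r.rbar_history
        for r in result.records
    }
    (outdir / f"{result.label}_rbar_histories.json").write_text(
        json.dumps(hist, indent=1)
    )


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

#: One-at-a-time repetitions: stiffness of cortex / ventral SFs up 30%,
#: activation shortening up 30% (activation value lowered), and per-bond
#: normal stiffness draws with CoV 30%.
SENSITIVITY_VARIANTS: dict[str, dict] = {
    "K_cortex_up": {
        "kind": "deterministic",
        "class": FibreClass.CORTEX,
        "K_t": 37.8,
    },
    "a_cortex_down": {
        "kind": "deterministic",
        "class": FibreClass.CORTEX,
        "a": 0.935,
    },
    "K_ventral_up": {
        "kind": "deterministic",
        "class": FibreClass.VENTRAL_SF,
        "K_t": 26.3,
    },
    "a_ventral_down": {
        "kind": "deterministic",
        "class": FibreClass.VENTRAL_SF,
        "a": 0.75,
    },
    "K_cortex_normal": {
        "kind": "probabilistic",
        "class": FibreClass.CORTEX,
        "cov": 0.30,
    },
    "K_ventral_normal": {
        "kind": "probabilistic",
        "class": FibreClass.VENTRAL_SF,
        "cov": 0.30,
    },
}


def apply_variant(
    net: CellNetwork, variant: dict, rng: np.random.Generator
) -> CellNetwork:
    """Return a copy of the network with one sensitivity variant applied."""
    cls: FibreClass = variant["class"]
    base = DEFAULT_MATERIALS[cls]
    if variant["kind"] == "deterministic":
        mat = BondMaterial(
            K_t=variant.get("K_t", base.K_t),
            K_c=0.1 * variant.get("K_t", base.K_t),
            a=variant.get("a", base.a),
        )
        return net.with_materials({cls: mat})
    if variant["kind"] == "probabilistic":
        mask = net.bond_class == cls.value
        K_t = net.K_t.copy()
        draws = rng.normal(base.K_t, variant["cov"] * base.K_t, size=mask.sum())
        draws[draws < 0.0] = 0.0  # rare negative draws are clipped to zero
        K_t[mask] = draws
        K_c = net.K_c.copy()
        K_c[mask] = 0.1 * draws
        return replace_fields(net, K_t=K_t, K_c=K_c)
    raise ValueError(f"unknown variant kind {variant['kind']!r}")


def sensitivity_study(
    config: StudyConfig = StudyConfig(),
    variants: dict[str, dict] | None = None,
    cells: list[CellNetwork] | None = None,
    control: StudyResult | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """One-at-a-time sensitivity analysis on a shared cell cohort.

    Returns a tidy table with, per variant and load case, the mean
    Delta eps_A (in %) and its relative change w.r.t. the control run.
    The same base networks are reused across all variants.
    """
    variants = SENSITIVITY_VARIANTS if variants is None else variants
    cells = generate_cohort(config) if cells is None else cells
    if control is None:
        control = replicate_tfm_study(config, cells=cells, verbose=verbose)

    rows = []
    for eps in config.load_cases:
        rows.append(
            {
                "variant": "control",
                "case": eps,
                "mean_delta_pct": 100.0 * control.mean_delta(eps),
                "relative_change": 0.0,
            }
        )
    for name, variant in variants.items():
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [config.seed, zlib.crc32(name.encode()) % 2**31]
            )
        )
        varied = [apply_variant(net, variant, rng) for net in cells]
        res = replicate_tfm_study(config, cells=varied, verbose=verbose)
        res.label = name
        for eps in config.load_cases:
            mean = res.mean_delta(eps)
            ctrl = control.mean_delta(eps)
            rows.append(
                {
                    "variant": name,
                    "case": eps,
                    "mean_delta_pct": 100.0 * mean,
                    "relative_change": (mean - ctrl) / ctrl,
                }
            )
    return pd.DataFrame(rows)
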