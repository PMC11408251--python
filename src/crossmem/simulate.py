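"""Coupled synthetic human / mouse datasets with planted structure.

The generator emulates the statistical skeleton of a cross-species design:
a human case-control cohort (default 32 patients, 16 controls) measured on
a probe-level blood expression array, a symptom-severity score on a
0-40-like intrusion-subscale scale, a mouse two-group (non-reactivated vs
reactivated) gene-level hippocampal expression matrix, and a candidate-gene
CpG beta-value matrix. Planted into this scaffold are:

* ``n_shared_signal`` genes present in both species whose human probes
  correlate with symptom severity at population magnitude
  ``human_effect_r`` and whose mouse genes change by ``mouse_log2fc``
  between groups, with a shared sign (negative by default, mirroring a
  cAMP-phosphodiesterase-like target that falls with symptom load);
* one designated target gene carrying a methylation -> expression ->
  symptom mediation chain with path coefficients ``mediation_a``,
  ``mediation_b`` and direct path ``mediation_cprime``;
* a co-expression block of ``coexpr_block_size`` probes sharing variance
  with the target at loading ``coexpr_loading``;
* one mediator CpG whose (latent, logistic-transformed) methylation drives
  the target gene; the remaining CpGs are independent noise.

All remaining probes/genes are independent Gaussian noise on the log2
scale; human matrices are emitted as raw intensities (2**log2) so the
standard normalization chain applies. Every random draw flows from
``SimulationConfig.seed`` through one :class:`numpy.random.Generator`, so
a fixed configuration reproduces the bundle bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticBundle",
    "generate_cohort",
    "write_bundle",
    "simulate_mediation_cohort",
]

MOUSE_CASE = "React-30"
MOUSE_CONTROL = "NR"


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one synthetic cohort.

    Counts mirror the emulated study design (32 patients / 16 controls;
    mouse groups of 8). Effect sizes default to the regime the integration
    gates are meant to detect: planted human probes at population
    |r| = 0.55 against the symptom score, planted mouse genes at
    |linear FC| = 1.5 (log2 ~ 0.585). ``noise_sd`` (log2-scale residual SD,
    default 0.14) was calibrated by a power simulation so that a planted
    mouse gene passes the q < 0.001, |FC| > 1.36 gate with probability
    about 0.9 at these sizes. ``effect_sign`` sets the shared direction of
    the planted effects (-1: expression falls as symptoms rise).
    ``mediation_noise_sd`` is the target gene's residual SD around its
    methylation-driven mean — the scale of the mediation chain itself,
    deliberately larger than probe noise so the methylation-expression
    association is strong but not collinear.
    """

    seed: int = 0
    n_patients: int = 32
    n_controls: int = 16
    n_probes: int = 20000
    n_mouse_genes: int = 18000
    n_shared_signal: int = 100
    human_effect_r: float = 0.55
    mouse_log2fc: float = 0.585
    mouse_n_per_group: int = 8
    noise_sd: float = 0.14
    mediation_a: float = 2.0
    mediation_b: float = -1.5
    mediation_cprime: float = 0.0
    mediation_noise_sd: float = 1.0
    coexpr_block_size: int = 30
    coexpr_loading: float = 0.8
    n_cpgs: int = 125
    effect_sign: int = -1
    target_symbol: str = "PDE4B"
    symptom_sd: float = 4.0
    missing_reexperiencing: bool = False

    def __post_init__(self) -> None:
        counts = {
            "n_patients": self.n_patients,
            "n_controls": self.n_controls,
            "n_probes": self.n_probes,
            "n_mouse_genes": self.n_mouse_genes,
            "n_shared_signal": self.n_shared_signal,
            "mouse_n_per_group": self.mouse_n_per_group,
            "coexpr_block_size": self.coexpr_block_size,
            "n_cpgs": self.n_cpgs,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_shared_signal > min(self.n_probes, self.n_mouse_genes):
            raise ValueError("n_shared_signal exceeds min(n_probes, n_mouse_genes)")
        if self.coexpr_block_size + self.n_shared_signal + 1 > self.n_probes:
            raise ValueError("planted probes (signal + block + target) exceed n_probes")
        if self.n_mouse_genes > 0 and self.n_shared_signal + 1 > self.n_mouse_genes:
            raise ValueError("planted mouse genes (signal + target) exceed n_mouse_genes")
        if self.noise_sd <= 0 or self.symptom_sd <= 0 or self.mediation_noise_sd <= 0:
            raise ValueError("noise parameters must be positive")
        if not 0 <= self.human_effect_r < 1:
            raise ValueError("human_effect_r must lie in [0, 1)")
        if not 0 <= self.coexpr_loading < 1:
            raise ValueError("coexpr_loading must lie in [0, 1)")
        if self.effect_sign not in (-1, 1):
            raise ValueError("effect_sign must be -1 or +1")
        if self.n_cpgs < 1:
            raise ValueError("need at least the mediator CpG")


@dataclass
class SyntheticBundle:
    """Generated datasets plus the ground truth planted into them."""

    config: SimulationConfig
    human_expr: ExpressionMatrix  # raw intensities, probes x subjects
    phenotypes: pd.DataFrame  # subjects x phenotype columns
    mouse_expr: ExpressionMatrix  # log2 expression, genes x animals, with groups
    methylation: pd.DataFrame  # CpGs x subjects, beta values in [0, 1]
    truth: dict[str, list[str] | str] = field(default_factory=dict)


def _probe_ids(n: int) -> list[str]:
    return [f"A_{i:07d}" for i in range(n)]


def generate_cohort(config: SimulationConfig) -> SyntheticBundle:
    """Draw one coupled human/mouse bundle from the generative model.

    Generation order: methylation latent and target expression; symptom
    scores (patients shifted upward, plus the mediation contributions);
    planted human probes as ``sign * beta * z(symptom) + noise`` with beta
    chosen so the population correlation magnitude equals
    ``human_effect_r``; the co-expression block as loading * standardized
    target expression plus noise; everything else independent noise.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_sub = cfg.n_patients + cfg.n_controls
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    subjects = [f"S{i:03d}" for i in range(1, n_sub + 1)]
    is_patient = np.zeros(n_sub, dtype=bool)
    is_patient[: cfg.n_patients] = True

    # --- methylation latent and target-gene expression (log2 scale) ---
    m_latent = rng.normal(size=n_sub)
    target_baseline = 8.0
    target_log2 = (
        target_baseline
        + cfg.mediation_a * m_latent
        + cfg.mediation_noise_sd * rng.normal(size=n_sub)
    )

    # --- symptom severity on a 0-40-like intrusion-subscale scale ---
    group_base = np.where(is_patient, 22.0, 4.0)
    symptom = (
        group_base
        + cfg.mediation_b * (target_log2 - target_baseline)
        + cfg.mediation_cprime * m_latent
        + cfg.symptom_sd * rng.normal(size=n_sub)
    )
    z = (symptom - symptom.mean()) / symptom.std(ddof=0)

    # --- human probe matrix ---
    n_signal = cfg.n_shared_signal
    n_block = cfg.coexpr_block_size
    probes = _probe_ids(cfg.n_probes)
    log2 = np.empty((cfg.n_probes, n_sub))
    baselines = rng.uniform(5.0, 12.0, size=cfg.n_probes)
    log2[:] = baselines[:, None] + cfg.noise_sd * rng.normal(size=(cfg.n_probes, n_sub))
    # probe 0: the target gene (mediation-driven)
    log2[0] = target_log2
    # probes 1..n_signal: planted shared-signal genes
    r = cfg.human_effect_r
    beta = cfg.noise_sd * r / np.sqrt(1.0 - r * r) if r > 0 else 0.0
    sig = slice(1, 1 + n_signal)
    log2[sig] = (
        baselines[sig, None]
        + cfg.effect_sign * beta * z[None, :]
        + cfg.noise_sd * rng.normal(size=(n_signal, n_sub))
    )
    # co-expression block around the target
    blk = slice(1 + n_signal, 1 + n_signal + n_block)
    zt = (target_log2 - target_log2.mean()) / target_log2.std(ddof=0)
    lam = cfg.coexpr_loading
    log2[blk] = (
        baselines[blk, None]
        + lam * zt[None, :]
        + np.sqrt(1.0 - lam * lam) * rng.normal(size=(n_block, n_sub))
    )

    symbols = np.array([f"GENE{i:06d}" for i in range(cfg.n_probes)], dtype=object)
    symbols[0] = cfg.target_symbol.upper()
    symbols[blk] = [f"COEX{i:04d}" for i in range(n_block)]
    human_expr = ExpressionMatrix(
        values=pd.DataFrame(
            np.power(2.0, log2), index=pd.Index(probes, name="probe_id"), columns=subjects
        ),
        symbols=pd.Series(symbols, index=probes, name="symbol"),
    )

    # --- phenotype table ---
    reexp = symptom.copy()
    pheno = pd.DataFrame(index=pd.Index(subjects, name="subject_id"))
    pheno["diagnosis"] = np.where(is_patient, "PTSD", "control")
    pheno["reexperiencing"] = reexp
    pheno["avoidance"] = 0.8 * reexp + 3.0 * rng.normal(size=n_sub)
    pheno["hyperarousal"] = 0.7 * reexp + 3.0 * rng.normal(size=n_sub)
    pheno["trait_anxiety"] = 40.0 + 6.0 * z + 6.0 * rng.normal(size=n_sub)
    pheno["state_anxiety"] = 40.0 + 8.0 * rng.normal(size=n_sub)
    pheno["depression"] = 10.0 + 5.0 * rng.normal(size=n_sub)
    pheno["age"] = rng.integers(21, 60, size=n_sub)
    if cfg.missing_reexperiencing and cfg.n_patients > 0:
        pheno.iloc[0, pheno.columns.get_loc("reexperiencing")] = np.nan

    # --- mouse matrix (log2 scale, two groups) ---
    n_animals = 2 * cfg.mouse_n_per_group
    animals = [f"M{i:02d}" for i in range(1, n_animals + 1)]
    group = np.array([MOUSE_CONTROL] * cfg.mouse_n_per_group + [MOUSE_CASE] * cfg.mouse_n_per_group)
    mouse_base = rng.uniform(4.0, 12.0, size=cfg.n_mouse_genes)
    mouse = mouse_base[:, None] + cfg.noise_sd * rng.normal(size=(cfg.n_mouse_genes, n_animals))
    react = group == MOUSE_CASE
    shift = cfg.effect_sign * cfg.mouse_log2fc
    # gene 0 = target, genes 1..n_signal = shared-signal genes
    if cfg.n_mouse_genes > 0:
        mouse[0, react] += shift
        mouse[1 : 1 + n_signal, react] += shift
    mouse_symbols = np.array(
        ["Gene" + f"{i:06d}" for i in range(cfg.n_mouse_genes)], dtype=object
    )
    mouse_symbols[0] = cfg.target_symbol.capitalize()
    mouse_expr = ExpressionMatrix(
        values=pd.DataFrame(
            mouse, index=pd.Index([f"mg{i:06d}" for i in range(cfg.n_mouse_genes)], name="gene_id"),
            columns=animals,
        ),
        symbols=pd.Series(mouse_symbols, index=[f"mg{i:06d}" for i in range(cfg.n_mouse_genes)],
                          name="symbol"),
        groups=pd.Series(group, index=animals, name="group"),
    )

    # --- candidate-gene CpG beta matrix (logistic-Gaussian, [0,1]) ---
    cpg_ids = [f"cg{i:08d}" for i in range(cfg.n_cpgs)]
    mu = rng.uniform(-2.0, 2.0, size=cfg.n_cpgs)
    latent = mu[:, None] + 0.5 * rng.normal(size=(cfg.n_cpgs, n_sub))
    latent[0] = -1.0 + 0.5 * m_latent  # mediator CpG tracks the latent driver
    meth = 1.0 / (1.0 + np.exp(-latent))
    methylation = pd.DataFrame(meth, index=pd.Index(cpg_ids, name="cpg_id"), columns=subjects)

    truth = {
        "signal_genes": [str(s) for s in symbols[sig]],
        "signal_probes": probes[1 : 1 + n_signal],
        "target_symbol": cfg.target_symbol.upper(),
        "target_probe": probes[0],
        "mediator_cpg": cpg_ids[0],
        "coexpr_probes": probes[1 + n_signal : 1 + n_signal + n_block],
        "symptom_scale": "0-40-like intrusion subscale",
    }
    return SyntheticBundle(
        config=cfg,
        human_expr=human_expr,
        phenotypes=pheno,
        mouse_expr=mouse_expr,
        methylation=methylation,
        truth=truth,
    )


def simulate_mediation_cohort(
    n: int,
    a: float,
    b: float,
    cprime: float = 0.0,
    noise_m: float = 1.0,
    noise_y: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linear-Gaussian X -> M -> Y triple for mediation calibration studies.

    X ~ N(0,1); M = a X + noise_m * e; Y = b M + cprime X + noise_y * e.
    The true indirect effect is a*b.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    m = a * x + noise_m * rng.normal(size=n)
    y = b * m + cprime * x + noise_y * rng.normal(size=n)
    return x, m, y


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle as tab-delimited files that round-trip via crossmem.io.

    Emits ``human_expression.tsv``, ``phenotypes.tsv``,
    ``mouse_expression.tsv``, ``mouse_samples.tsv``, ``methylation.tsv``,
    ``truth.tsv`` and ``config.yaml``; returns the path of each.
    """
    from . import io as cio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "human_expression": directory / "human_expression.tsv",
        "phenotypes": directory / "phenotypes.tsv",
        "mouse_expression": directory / "mouse_expression.tsv",
        "mouse_samples": directory / "mouse_samples.tsv",
        "methylation": directory / "methylation.tsv",
        "truth": directory / "truth.tsv",
        "config": directory / "config.yaml",
    }
    cio.write_expression(bundle.human_expr, paths["human_expression"])
    cio.write_phenotypes(bundle.phenotypes, paths["phenotypes"])
    cio.write_expression(
        bundle.mouse_expr, paths["mouse_expression"], groups_path=paths["mouse_samples"]
    )
    cio.write_methylation(bundle.methylation, paths["methylation"])

    rows = []
    for kind, ids in bundle.truth.items():
        if isinstance(ids, str):
            rows.append({"kind": kind, "id": ids})
        else:
            rows.extend({"kind": kind, "id": i} for i in ids)
    pd.DataFrame(rows, columns=["kind", "id"]).to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(dataclasses.asdict(bundle.config), fh, sort_keys=False)
    return paths
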