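"""Ground-truth-labeled synthetic data emulating the developing cerebellum,
its spatial sections, and Patched-like tumors.

The generator plants a small number of interpretable structures so that
every downstream procedure has a recoverable truth:

* **States.**  Cells belong to one of ``n_states`` granule-lineage states
  arranged along a differentiation chain (dividing progenitors ->
  non-dividing progenitors -> migrating neurons -> mature neurons).  Each
  state owns a disjoint signature gene set whose expected expression is
  multiplied by ``exp(effect_lnfc)`` in cells of that state.  A separate
  cycling program is up-regulated in a state-dependent fraction of cells.
* **Counts.**  UMI counts are negative-binomial (gamma-Poisson) with a
  global dispersion; library sizes are log-normal; a configurable
  fraction of genes carries a mitochondrial name prefix so QC filters
  have something to act on.
* **Spots.**  Multi-cell capture spots draw exactly ``spot_cells`` member
  cells from layer-specific state compositions; a spot's gene vector is
  the exact sum of its members' counts, and spots sit on a grid
  partitioned into contiguous layer bands.
* **Kinetics.**  Spliced/unspliced abundances follow the first-order
  two-rate model du/dt = alpha - beta*u, ds/dt = beta*u - gamma*s, with
  each cell's phase (induction, repression, basal steady state) set by
  its state, its pseudotime and its planted fate draw from the Markov
  transition kernel, so that the sign of the velocity residual encodes
  the planted direction along the chain.
* **Tumors.**  Tumor cells reuse the developmental programs under a
  self-renewal-biased kernel, add a metabolic program in a subset of
  malignant cells, and multiply genes on CNV-affected chromosomes by
  ``exp(shift)``; a configurable fraction of non-malignant cells carries
  neither CNV nor metabolic program.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .core_io import CountMatrix, SpotMatrix
from .velocity import KineticsMatrix

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_reference_cells",
    "generate_spots",
    "generate_kinetics",
    "generate_tumor_cells",
    "DEFAULT_STATE_NAMES",
    "DEFAULT_LAYER_NAMES",
]

DEFAULT_STATE_NAMES = (
    "GNP_dividing",
    "GNP_nondividing",
    "GN_migrating",
    "GN_mature",
)
DEFAULT_LAYER_NAMES = ("EGL_outer", "EGL_inner", "ML_PCL", "IGL")



class ConfigurationError(ValueError):
    pass


def _chain_kernel(n_states: int, self_prob: float) -> np.ndarray:
    """Row-stochastic chain kernel: stay with self_prob, else step forward."""
    k = np.zeros((n_states, n_states))
    for i in range(n_states - 1):
        k[i, i] = self_prob
        k[i, i + 1] = 1.0 - self_prob
    k[-1, -1] = 1.0
    return k


def _default_layer_composition(n_states: int) -> pd.DataFrame:
    if n_states != 4:
        # diagonal-dominant fallback for non-default state counts
        comp = np.full((n_states, n_states), 0.25 / max(n_states - 1, 1))
        np.fill_diagonal(comp, 0.75)
        comp /= comp.sum(axis=1, keepdims=True)
        layers = [f"layer_{i}" for i in range(n_states)]
        return pd.DataFrame(comp, index=layers, columns=range(n_states))
    comp = np.array(
        [
            [0.75, 0.17, 0.05, 0.03],
            [0.15, 0.70, 0.12, 0.03],
            [0.03, 0.12, 0.70, 0.15],
            [0.02, 0.05, 0.18, 0.75],
        ]
    )
    return pd.DataFrame(comp, index=list(DEFAULT_LAYER_NAMES), columns=range(4))


@dataclass
class SimConfig:
    """All knobs of the synthetic generator; defaults are the study conditions.

    ``transition_kernel`` rows are per-state next-state probabilities along
    the differentiation chain (development: 0.3 self-renewal for every
    non-terminal state).  ``layer_composition`` rows are per-layer state
    mixtures for spot generation.  ``cnv_events`` is a list of
    ``(chromosome, ln_shift)`` pairs applied to malignant cells only.
    """

    n_cells: int = 1000
    n_genes: int = 2000
    n_states: int = 4
    signature_size_per_state: int = 50
    cycling_size: int = 50
    metabolic_size: int = 50
    effect_lnfc: float = 1.0
    state_prior: tuple[float, ...] | None = None
    cycling_fraction_per_state: tuple[float, ...] | None = None
    libsize_lognormal: tuple[float, float] = (np.log(10_000.0), 0.25)
    nb_dispersion: float = 10.0
    mito_gene_fraction: float = 0.01
    transition_kernel: np.ndarray | None = None
    spot_cells: int = 30
    spots_per_layer: int = 40
    layer_composition: pd.DataFrame | None = None
    cnv_events: tuple[tuple[str, float], ...] = ()
    malignant_fraction: float = 1.0
    metabolic_fraction: float = 0.0
    kinetics_noise: float = 0.1
    n_chromosomes: int = 5
    seed: int = 0
    state_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.state_names is None:
            self.state_names = (
                DEFAULT_STATE_NAMES
                if self.n_states == 4
                else tuple(f"state_{i}" for i in range(self.n_states))
            )
        if self.state_prior is None:
            self.state_prior = tuple([1.0 / self.n_states] * self.n_states)
        if self.cycling_fraction_per_state is None:
            frac = [0.02] * self.n_states
            frac[0] = 0.80
            if self.n_states > 1:
                frac[1] = 0.10
            self.cycling_fraction_per_state = tuple(frac)
        if self.transition_kernel is None:
            self.transition_kernel = _chain_kernel(self.n_states, 0.3)
        self.transition_kernel = np.asarray(self.transition_kernel, dtype=float)
        if self.layer_composition is None:
            self.layer_composition = _default_layer_composition(self.n_states)
        self.validate()

    def validate(self) -> None:
        if self.effect_lnfc <= 0:
            raise ConfigurationError("effect_lnfc must be > 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        reserved = (
            self.n_states * self.signature_size_per_state
            + self.cycling_size
            + self.metabolic_size
        )
        if reserved > self.n_genes:
            raise ConfigurationError(
                f"{reserved} program genes exceed n_genes={self.n_genes}"
            )
        for name, mat in (
            ("transition_kernel", self.transition_kernel),
            ("layer_composition", self.layer_composition.to_numpy()),
        ):
            mat = np.asarray(mat, dtype=float)
            if mat.shape[-1] != self.n_states:
                raise ConfigurationError(f"{name} must have {self.n_states} columns")
            if (mat < 0).any() or np.abs(mat.sum(axis=1) - 1).max() > 1e-9:
                raise ConfigurationError(f"{name} rows must be stochastic")
        if not np.isclose(sum(self.state_prior), 1.0):
            raise ConfigurationError("state_prior must sum to 1")
        for f in self.cycling_fraction_per_state:
            if not 0 <= f <= 1:
                raise ConfigurationError("cycling fractions must be in [0, 1]")
        if not 0 <= self.mito_gene_fraction <= 1:
            raise ConfigurationError("mito_gene_fraction must be in [0, 1]")

    # -- config file round trip (flat YAML) --------------------------
    def to_yaml(self, path: str | Path) -> None:
        def plain(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, (tuple, list)):
                return [plain(i) for i in v]
            return v

        d = {k: plain(v) for k, v in dataclasses.asdict(self).items()}
        d["transition_kernel"] = np.asarray(self.transition_kernel).tolist()
        d["layer_composition"] = {
            str(k): list(map(float, v))
            for k, v in self.layer_composition.iterrows()
        }
        d["cnv_events"] = [[c, float(s)] for c, s in self.cnv_events]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("layer_composition") is not None:
            lc = pd.DataFrame.from_dict(d["layer_composition"], orient="index")
            d["layer_composition"] = lc
        if d.get("transition_kernel") is not None:
            d["transition_kernel"] = np.asarray(d["transition_kernel"])
        d["cnv_events"] = tuple((c, s) for c, s in d.get("cnv_events", []))
        for key in ("state_prior", "cycling_fraction_per_state", "state_names",
                    "libsize_lognormal"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted truth labels for a generated dataset."""

    cell_state: pd.Series  # cell -> state name
    cell_pseudotime: pd.Series  # cell -> [0, 1] position within its state
    cell_fate: pd.Series  # cell -> planted next state (kernel draw)
    cell_cycling: pd.Series  # cell -> bool
    tumor_flag: pd.Series  # cell -> bool (malignant)
    gene_program: pd.Series  # gene -> program label or "background"
    state_signatures: dict[str, list[str]]  # state name -> signature genes
    programs: dict[str, list[str]]  # all planted programs incl. cycling etc.
    spot_layer: pd.Series | None = None  # spot -> layer name
    spot_members: dict[str, list[str]] | None = None
    dsdt: pd.DataFrame | None = None  # noise-free true ds/dt, cells x genes
    kinetic_rates: pd.DataFrame | None = None  # gene -> alpha, beta, gamma
    metabolic_cells: pd.Series | None = None  # tumor only: cells with the program


# ---------------------------------------------------------------------
# gene universe


def _build_gene_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene names, program labels, chromosomes/starts and baseline weights."""
    G = config.n_genes
    m = config.signature_size_per_state
    names: list[str] = []
    program: list[str] = []
    for k in range(config.n_states):
        state = config.state_names[k]
        names += [f"Sig{k}.{i:03d}" for i in range(m)]
        program += [state] * m
    names += [f"Cyc.{i:03d}" for i in range(config.cycling_size)]
    program += ["cycling"] * config.cycling_size
    names += [f"Met.{i:03d}" for i in range(config.metabolic_size)]
    program += ["metabolic"] * config.metabolic_size
    n_mito = int(round(config.mito_gene_fraction * G))
    n_mito = min(n_mito, G - len(names))
    names += [f"mt-Gene{i:03d}" for i in range(n_mito)]
    program += ["mito"] * n_mito
    n_ribo = min(20, G - len(names))
    names += [f"Rps{i:03d}" for i in range(n_ribo)]
    program += ["ribo"] * n_ribo
    n_bg = G - len(names)
    names += [f"Bg.{i:04d}" for i in range(n_bg)]
    program += ["background"] * n_bg

    # chromosomes round-robin so every program is spread over the genome;
    # few, large synthetic chromosomes keep the genes-per-chromosome to
    # smoothing-window ratio in the regime of real genomes
    n_chrom = config.n_chromosomes
    chrom = [f"chr{(i % n_chrom) + 1}" for i in range(G)]
    start = [(i // n_chrom + 1) * 100_000 for i in range(G)]

    weight = np.exp(rng.normal(0.0, 1.0, size=G))
    prog = np.asarray(program, dtype=object)
    weight[np.isin(prog, list(config.state_names) + ["cycling", "metabolic"])] = 8.0
    weight[prog == "mito"] = 12.0
    weight[prog == "ribo"] = 10.0
    return pd.DataFrame(
        {
            "gene": names,
            "program": program,
            "chromosome": chrom,
            "start": start,
            "weight": weight,
        }
    ).set_index("gene")


def _draw_cells(
    config: SimConfig, rng: np.random.Generator, n_cells: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(state index, pseudotime, fate index, cycling flag) per cell."""
    states = rng.choice(config.n_states, size=n_cells, p=list(config.state_prior))
    tau = rng.uniform(0.0, 1.0, size=n_cells)
    kernel = np.asarray(config.transition_kernel)
    fates = np.array([rng.choice(config.n_states, p=kernel[s]) for s in states])
    cyc_frac = np.asarray(config.cycling_fraction_per_state)
    cycling = rng.uniform(size=n_cells) < cyc_frac[states]
    return states, tau, fates, cycling


def _expected_weights(
    config: SimConfig,
    genes: pd.DataFrame,
    states: np.ndarray,
    cycling: np.ndarray,
    malignant: np.ndarray | None = None,
    metabolic: np.ndarray | None = None,
) -> np.ndarray:
    """Cells x genes expected relative-abundance weights."""
    base = genes["weight"].to_numpy()
    prog = genes["program"].to_numpy(object)
    n_cells = len(states)
    w = np.tile(base, (n_cells, 1))
    boost = np.exp(config.effect_lnfc)
    for k, state in enumerate(config.state_names):
        cols = prog == state
        w[np.ix_(states == k, cols)] *= boost
    w[np.ix_(cycling, prog == "cycling")] *= boost
    if metabolic is not None and metabolic.any():
        w[np.ix_(metabolic, prog == "metabolic")] *= boost
    # Mass-neutral program boosts: rescale non-program genes so every
    # cell's total weight equals the baseline total.  Relative abundances
    # of boosted genes then differ between groups by exactly
    # exp(effect_lnfc) instead of being diluted by each cell's own boost
    # mass.  CNV mass is deliberately NOT compensated: a genomic gain
    # raises total transcript output and dilutes the rest of the
    # transcriptome under library-size normalization, as in real data.
    bg = np.isin(prog, ["background", "mito", "ribo"])
    target = base.sum()
    extra = w.sum(axis=1) - target
    bg_mass = w[:, bg].sum(axis=1)
    factor = np.maximum((bg_mass - extra) / bg_mass, 0.05)
    w[:, bg] *= factor[:, None]
    if malignant is not None and config.cnv_events:
        chroms = genes["chromosome"].to_numpy(object)
        for chrom, shift in config.cnv_events:
            cols = chroms == chrom
            if not cols.any():
                raise ConfigurationError(f"CNV chromosome {chrom!r} has no genes")
            w[np.ix_(malignant, cols)] *= np.exp(shift)
    return w


def _sample_counts(
    config: SimConfig, rng: np.random.Generator, weights: np.ndarray
) -> sp.csr_matrix:
    """Gamma-Poisson counts with log-normal library sizes."""
    mu, sigma = config.libsize_lognormal
    libsize = rng.lognormal(mu, sigma, size=weights.shape[0])
    p = weights / weights.sum(axis=1, keepdims=True)
    mean = libsize[:, None] * p
    theta = config.nb_dispersion
    lam = rng.gamma(theta, mean / theta)
    counts = rng.poisson(lam)
    return sp.csr_matrix(counts)


def _make_truth(
    config: SimConfig,
    genes: pd.DataFrame,
    cell_ids: np.ndarray,
    states: np.ndarray,
    tau: np.ndarray,
    fates: np.ndarray,
    cycling: np.ndarray,
    malignant: np.ndarray,
) -> GroundTruth:
    state_names = np.asarray(config.state_names, dtype=object)
    prog = genes["program"]
    sigs = {
        s: genes.index[prog == s].tolist() for s in config.state_names
    }
    programs = dict(sigs)
    programs["cycling"] = genes.index[prog == "cycling"].tolist()
    if config.metabolic_size:
        programs["metabolic"] = genes.index[prog == "metabolic"].tolist()
    return GroundTruth(
        cell_state=pd.Series(state_names[states], index=cell_ids, name="state"),
        cell_pseudotime=pd.Series(tau, index=cell_ids, name="pseudotime"),
        cell_fate=pd.Series(state_names[fates], index=cell_ids, name="fate"),
        cell_cycling=pd.Series(cycling, index=cell_ids, name="cycling"),
        tumor_flag=pd.Series(malignant, index=cell_ids, name="malignant"),
        gene_program=prog.copy(),
        state_signatures=sigs,
        programs=programs,
    )


def _gene_meta(genes: pd.DataFrame) -> pd.DataFrame:
    meta = genes[["chromosome", "start"]].copy()
    meta["is_mito"] = genes["program"] == "mito"
    meta["is_ribo"] = genes["program"] == "ribo"
    return meta


def generate_reference_cells(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial counts for the developmental reference population.

    State-k cells carry an ``exp(effect_lnfc)`` multiplier on their state
    signature genes; cycling cells additionally up-regulate the cycling
    program.  Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _build_gene_table(config, rng)
    states, tau, fates, cycling = _draw_cells(config, rng, config.n_cells)
    weights = _expected_weights(config, genes, states, cycling)
    counts = _sample_counts(config, rng, weights)
    cell_ids = np.array(
        [f"c{config.seed}-{i:05d}" for i in range(config.n_cells)], dtype=object
    )
    cm = CountMatrix(counts, cell_ids, genes.index.to_numpy(object), _gene_meta(genes))
    truth = _make_truth(
        config, genes, cell_ids, states, tau, fates, cycling,
        malignant=np.zeros(config.n_cells, dtype=bool),
    )
    return cm, truth


# ---------------------------------------------------------------------
# spatial spots


def generate_spots(
    config: SimConfig, cells: CountMatrix, truth: GroundTruth
) -> tuple[SpotMatrix, GroundTruth]:
    """Multi-cell spots drawn from layer-specific state compositions.

    Every spot has exactly ``config.spot_cells`` members sampled from the
    layer's state mixture; its gene vector is the exact element-wise sum
    of the member cells' counts.  Spots are laid out on a grid whose rows
    form contiguous bands, one band per layer.  Returns the spot matrix
    and a copy of ``truth`` extended with spot-level fields.
    """
    comp = config.layer_composition
    state_names = list(config.state_names)
    state_of = truth.cell_state.to_numpy(object)
    pool = {
        s: np.flatnonzero(state_of == s) for s in state_names
    }
    rng = np.random.default_rng(config.seed + 1)
    spot_rows = []
    spot_ids, layers_out, members_out = [], [], {}
    coords = []
    n_col = 10
    y_offset = 0
    for layer, row in comp.iterrows():
        probs = row.to_numpy(float)
        for j in range(config.spots_per_layer):
            n_per_state = rng.multinomial(config.spot_cells, probs)
            member_idx: list[int] = []
            for k, n_k in enumerate(n_per_state):
                if n_k == 0:
                    continue
                avail = pool[state_names[k]]
                if len(avail) < n_k:
                    raise ConfigurationError(
                        f"layer {layer!r} needs {n_k} cells of state "
                        f"{state_names[k]!r} but only {len(avail)} exist"
                    )
                member_idx.extend(rng.choice(avail, size=n_k, replace=False))
            sid = f"spot_{layer}_{j:03d}"
            spot_ids.append(sid)
            layers_out.append(layer)
            members_out[sid] = [cells.cell_ids[i] for i in member_idx]
            spot_rows.append(
                np.asarray(cells.values[member_idx].sum(axis=0)).ravel()
            )
            coords.append((j % n_col, y_offset + j // n_col))
        y_offset += (config.spots_per_layer + n_col - 1) // n_col
    values = sp.csr_matrix(np.vstack(spot_rows))
    coords_df = pd.DataFrame(coords, columns=["x", "y"], index=spot_ids)
    coords_df["layer"] = layers_out
    sm = SpotMatrix(
        values,
        np.asarray(spot_ids, dtype=object),
        cells.gene_ids,
        cells.gene_meta,
        coords_df,
    )
    out = dataclasses.replace(
        truth,
        spot_layer=pd.Series(layers_out, index=spot_ids, name="layer"),
        spot_members=members_out,
    )
    return sm, out


# ---------------------------------------------------------------------
# two-rate kinetics


def _induction(alpha, beta, gamma, t):
    """u, s for induction from zero at time t (beta != gamma)."""
    u = alpha / beta * (1.0 - np.exp(-beta * t))
    s = alpha / gamma * (1.0 - np.exp(-gamma * t)) + alpha / (gamma - beta) * (
        np.exp(-gamma * t) - np.exp(-beta * t)
    )
    return u, s

def _repression(u0, s0, beta, gamma, t):
    """u, s after switching transcription off at u0, s0 (beta != gamma)."""
    u = u0 * np.exp(-beta * t)
    s = s0 * np.exp(-gamma * t) + beta * u0 / (gamma - beta) * (
        np.exp(-beta * t) - np.exp(-gamma * t)
    )
    return u, s


T_INDUCTION = 3.0  # on-phase duration in units of the gene's 1/gamma
BASAL_FRACTION = 0.1  # basal transcription relative to the on state


def generate_kinetics(config: SimConfig, truth: GroundTruth) -> KineticsMatrix:
    """Spliced/unspliced abundances consistent with the planted fates.

    Per gene, rates are sampled positive (beta > gamma, splicing faster
    than degradation).  For a cell in state k: if its planted fate is
    self-renewal, its own signature genes are mid-induction (velocity
    residual > 0 toward its own program); if the fate is the chain
    successor, its own signature genes are in repression and the
    successor's are in early induction, so the velocity points along the
    chain.  All other genes sit at a basal steady state (zero velocity).
    Multiplicative log-normal noise (``config.kinetics_noise``) preserves
    non-negativity; set it to 0 for the exact closed-form solution.
    """
    rng = np.random.default_rng(config.seed + 2)
    gene_ids = truth.gene_program.index.to_numpy(object)
    G = len(gene_ids)
    n = len(truth.cell_state)
    alpha = rng.uniform(5.0, 15.0, size=G)
    beta = rng.uniform(1.0, 2.0, size=G)
    gamma = rng.uniform(0.3, 0.8, size=G)
    if (alpha <= 0).any() or (beta <= 0).any() or (gamma <= 0).any():
        raise ConfigurationError("kinetic rates must be positive")

    state_names = list(config.state_names)
    prog = truth.gene_program.to_numpy(object)
    gene_state = np.full(G, -1)
    for k, s in enumerate(state_names):
        gene_state[prog == s] = k
    states = np.array([state_names.index(s) for s in truth.cell_state])
    fates = np.array([state_names.index(s) for s in truth.cell_fate])
    tau = truth.cell_pseudotime.to_numpy(float)

    # basal steady state everywhere, then overwrite program genes
    a_b = BASAL_FRACTION * alpha
    u = np.tile(a_b / beta, (n, 1))
    s_mat = np.tile(a_b / gamma, (n, 1))
    dsdt = np.zeros((n, G))

    is_state_gene = gene_state >= 0
    for i in range(n):
        k, f, t_frac = states[i], fates[i], tau[i]
        own = is_state_gene & (gene_state == k)
        # phase times scale with each gene's own degradation rate so that
        # late-pseudotime cells approach the true steady state
        if f == k:
            # self-renewal: own program mid-induction, still rising
            t = (0.15 + 0.85 * t_frac) * T_INDUCTION / gamma[own]
            u[i, own], s_mat[i, own] = _induction(
                alpha[own], beta[own], gamma[own], t
            )
        else:
            # transition: own program switched off from steady state,
            # successor program in early induction
            t_off = (0.1 + 0.6 * t_frac) * 0.7 * T_INDUCTION / gamma[own]
            u0, s0 = alpha[own] / beta[own], alpha[own] / gamma[own]
            u[i, own], s_mat[i, own] = _repression(
                u0, s0, beta[own], gamma[own], t_off
            )
            succ = is_state_gene & (gene_state == f)
            t_on = (0.1 + 0.5 * t_frac) * 0.5 * T_INDUCTION / gamma[succ]
            u[i, succ], s_mat[i, succ] = _induction(
                alpha[succ], beta[succ], gamma[succ], t_on
            )
        dsdt[i] = beta * u[i] - gamma * s_mat[i]

    if config.kinetics_noise > 0:
        u = u * rng.lognormal(0.0, config.kinetics_noise, size=u.shape)
        s_mat = s_mat * rng.lognormal(0.0, config.kinetics_noise, size=s_mat.shape)

    truth.dsdt = pd.DataFrame(dsdt, index=truth.cell_state.index, columns=gene_ids)
    truth.kinetic_rates = pd.DataFrame(
        {"alpha": alpha, "beta": beta, "gamma": gamma}, index=gene_ids
    )
    return KineticsMatrix(
        spliced=s_mat,
        unspliced=u,
        cell_ids=truth.cell_state.index.to_numpy(object),
        gene_ids=gene_ids,
    )


# ---------------------------------------------------------------------
# tumors


def generate_tumor_cells(
    config: SimConfig,
) -> tuple[CountMatrix, KineticsMatrix, GroundTruth]:
    """Tumor counts + kinetics: developmental programs, biased kernel, CNVs.

    Malignant cells (fraction ``config.malignant_fraction``) follow
    ``config.transition_kernel`` (pass a self-renewal-biased kernel for
    the tumor condition), carry the planted CNV shifts and, for a random
    ``metabolic_fraction`` of them, the metabolic program.  Non-malignant
    cells follow the developmental chain kernel and carry no CNV.  With
    zero CNV events, full malignancy and the developmental kernel the
    output is statistically identical to the reference generator.
    """
    if config.cnv_events and config.malignant_fraction < 1.0:
        pass  # normal cells present: CNV detectable against them
    rng = np.random.default_rng(config.seed)
    genes = _build_gene_table(config, rng)
    n = config.n_cells
    states, tau, fates, cycling = _draw_cells(config, rng, n)
    malignant = rng.uniform(size=n) < config.malignant_fraction
    # non-malignant cells follow the unbiased developmental chain
    dev_kernel = _chain_kernel(config.n_states, 0.3)
    for i in np.flatnonzero(~malignant):
        fates[i] = rng.choice(config.n_states, p=dev_kernel[states[i]])
    metabolic = malignant & (rng.uniform(size=n) < config.metabolic_fraction)
    weights = _expected_weights(
        config, genes, states, cycling, malignant=malignant, metabolic=metabolic
    )
    counts = _sample_counts(config, rng, weights)
    cell_ids = np.array([f"t{config.seed}-{i:05d}" for i in range(n)], dtype=object)
    cm = CountMatrix(counts, cell_ids, genes.index.to_numpy(object), _gene_meta(genes))
    truth = _make_truth(
        config, genes, cell_ids, states, tau, fates, cycling, malignant
    )
    truth.gene_program = truth.gene_program.copy()
    if config.cnv_events:
        chroms = genes["chromosome"]
        for chrom, _shift in config.cnv_events:
            affected = chroms == chrom
            lbl = truth.gene_program[affected].astype(str) + "+cnv"
            truth.gene_program.loc[affected] = lbl
    truth.metabolic_cells = pd.Series(metabolic, index=cell_ids, name="metabolic")
    kin = generate_kinetics(config, truth)
    return cm, kin, truth
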