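"""Synthetic paired clinical/molecular datasets with planted bad neighborhoods.

The generator emulates the structure of tumor-classification studies that
pair a handful of mixed-type clinical covariates with a high-dimensional
expression matrix:

* a low-dimensional clinical block (continuous, binary, nominal, ordinal
  variables, each carrying a class mean shift);
* a ``p``-dimensional continuous molecular block whose first
  ``n_molecular_signal`` features carry the class signal;
* cross-space correlation ``rho``: clinical continuous signal features and
  molecular signal features both load on shared latent factors with loading
  sqrt(rho), so conditional on the class their correlation is rho;
* planted within-class subgroups ("bad neighborhoods"): a fraction of one
  class whose features *in one space only* are drawn from the opposite
  class's distribution there, displaced by a fixed cluster offset orthogonal
  to the class axis.  Such samples are misclassifiable in the misleading
  space but not in the other, and they form a coherent cluster rather than
  scattering through the opposite class -- the situation the re-classification
  score is designed to detect.

Categorical clinical variables are produced by thresholding latent normals
that carry the class shift, so they are informative without a separate
mechanism.  Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ClinicalSchema, ClinicalTable, LabeledDataset, MolecularMatrix

SUBGROUP_SPACES = ("clinical", "molecular", "both")


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclasses.dataclass(frozen=True)
class SubgroupSpec:
    """A planted subgroup: ``fraction`` of class ``cls`` misleading in ``space``."""

    cls: int
    fraction: float
    space: str

    def __post_init__(self) -> None:
        if self.cls not in (0, 1):
            raise ConfigError(f"subgroup class must be 0 or 1, got {self.cls}")
        if not 0.0 < self.fraction < 1.0:
            raise ConfigError(f"subgroup fraction must be in (0, 1), got {self.fraction}")
        if self.space not in SUBGROUP_SPACES:
            raise ConfigError(
                f"subgroup space must be one of {SUBGROUP_SPACES}, got {self.space!r}")

    @property
    def tag(self) -> str:
        return f"{self.space}_misleading_class{self.cls}"


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    n_samples: int = 120
    n_continuous: int = 5
    n_binary: int = 2
    n_nominal: int = 1
    nominal_levels: int = 3
    n_ordinal: int = 1
    ordinal_levels: int = 4
    n_molecular: int = 300
    n_molecular_signal: int = 30
    class_balance: float = 0.5          # fraction of class 1
    clinical_effect: float = 1.0        # class mean shift, in SD units
    molecular_effect: float = 0.5
    rho: float = 0.0                    # clinical-molecular correlation
    subgroups: tuple[SubgroupSpec, ...] = ()
    subgroup_shift: float = 1.5         # cluster offset norm, orthogonal to class axis
    clinical_noise: float = 1.0
    molecular_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ConfigError("need at least 4 samples")
        if not 0.0 < self.class_balance < 1.0:
            raise ConfigError("class_balance must be in (0, 1)")
        n_pos = int(round(self.n_samples * self.class_balance))
        if n_pos < 2 or self.n_samples - n_pos < 2:
            raise ConfigError("class_balance leaves a class with < 2 samples")
        if not 0.0 <= self.rho < 1.0:
            raise ConfigError("rho must be in [0, 1)")
        if self.n_continuous < 1:
            raise ConfigError("need at least one continuous clinical feature")
        if self.n_molecular_signal > self.n_molecular:
            raise ConfigError("n_molecular_signal exceeds n_molecular")
        for space in ("clinical", "molecular"):
            for cls in (0, 1):
                total = sum(s.fraction for s in self.subgroups
                            if s.cls == cls and s.space in (space, "both"))
                if total >= 1.0:
                    raise ConfigError(
                        f"subgroup fractions for class {cls} in {space} space sum to "
                        f"{total:.2f} >= 1")


def _assign_labels(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    n_pos = int(round(cfg.n_samples * cfg.class_balance))
    if n_pos < 2 or cfg.n_samples - n_pos < 2:
        raise ConfigError("class balance leaves a class with < 2 samples")
    y = np.zeros(cfg.n_samples, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)
    return y


def _assign_subgroups(cfg: GeneratorConfig, y: np.ndarray,
                      rng: np.random.Generator) -> list[str]:
    """One tag per sample: 'none' or the subgroup's tag.  A sample belongs to
    at most one subgroup."""
    tags = ["none"] * cfg.n_samples
    available = {0: list(np.flatnonzero(y == 0)), 1: list(np.flatnonzero(y == 1))}
    for sub in cfg.subgroups:
        pool = available[sub.cls]
        k = int(round(sub.fraction * int((y == sub.cls).sum())))
        if k > len(pool):
            raise ConfigError(f"subgroup {sub.tag} larger than remaining class members")
        chosen = rng.choice(len(pool), size=k, replace=False)
        for idx in sorted(chosen, reverse=True):
            sample = pool.pop(int(idx))
            tags[sample] = sub.tag
    return tags


def _orthogonal_offset(dim: int, shift: float, rng: np.random.Generator) -> np.ndarray:
    """A direction of norm ``shift`` orthogonal to the class axis (the
    all-ones direction along which the mean shift acts)."""
    if dim == 1:
        return np.zeros(1)
    v = rng.standard_normal(dim)
    ones = np.ones(dim) / np.sqrt(dim)
    v -= (v @ ones) * ones
    norm = np.linalg.norm(v)
    if norm < 1e-12:  # pragma: no cover - measure-zero event
        v = np.zeros(dim)
        v[0], v[1] = 1.0, -1.0
        norm = np.sqrt(2.0)
    return v / norm * shift


def generate(cfg: GeneratorConfig, seed: int | None = None
             ) -> tuple[LabeledDataset, pd.DataFrame]:
    """Generate a dataset and its ground-truth annotations.

    Returns the aligned dataset (clinical + molecular + labels) and a frame
    indexed by sample id with columns ``label`` and ``subgroup``.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_samples
    y = _assign_labels(cfg, rng)
    tags = _assign_subgroups(cfg, y, rng)

    # per-sample class sign in each space (+1 class 1, -1 class 0; flipped
    # for samples misleading in that space)
    sign = y * 2.0 - 1.0
    s_clin, s_mol = sign.copy(), sign.copy()
    in_clin_sub = np.array([t.startswith(("clinical", "both")) for t in tags])
    in_mol_sub = np.array([t.startswith(("molecular", "both")) for t in tags])
    s_clin[in_clin_sub] *= -1.0
    s_mol[in_mol_sub] *= -1.0

    # shared latent factors linking the two spaces
    q = cfg.n_continuous
    z = rng.standard_normal((n, q))
    a, b = np.sqrt(cfg.rho), np.sqrt(1.0 - cfg.rho)

    # cluster offsets, one fixed direction per subgroup per space
    clin_offsets = {sub.tag: _orthogonal_offset(cfg.n_continuous, cfg.subgroup_shift, rng)
                    for sub in cfg.subgroups if sub.space in ("clinical", "both")}
    mol_offsets = {sub.tag: _orthogonal_offset(cfg.n_molecular_signal, cfg.subgroup_shift, rng)
                   for sub in cfg.subgroups if sub.space in ("molecular", "both")}

    # --- clinical block -----------------------------------------------------
    half_c = 0.5 * cfg.clinical_effect
    cont = (half_c * s_clin[:, None]
            + a * z
            + b * cfg.clinical_noise * rng.standard_normal((n, q)))
    for tag, offset in clin_offsets.items():
        rows = np.array([t == tag for t in tags])
        cont[rows] += offset

    columns: dict[str, object] = {}
    kinds: dict[str, str] = {}
    ordinal_levels: dict[str, tuple[str, ...]] = {}
    for j in range(cfg.n_continuous):
        columns[f"c{j + 1}"] = cont[:, j]
        kinds[f"c{j + 1}"] = "continuous"

    def _latent() -> np.ndarray:
        return half_c * s_clin + rng.standard_normal(n)

    from scipy.stats import norm

    for j in range(cfg.n_binary):
        col = np.where(_latent() > 0.0, "pos", "neg")
        columns[f"b{j + 1}"] = col
        kinds[f"b{j + 1}"] = "binary"
    for j in range(cfg.n_nominal):
        cuts = norm.ppf(np.linspace(0, 1, cfg.nominal_levels + 1)[1:-1])
        codes = np.digitize(_latent(), cuts)
        columns[f"nom{j + 1}"] = np.array([f"lv{c}" for c in codes])
        kinds[f"nom{j + 1}"] = "nominal"
    for j in range(cfg.n_ordinal):
        cuts = norm.ppf(np.linspace(0, 1, cfg.ordinal_levels + 1)[1:-1])
        codes = np.digitize(_latent(), cuts)
        levels = tuple(f"g{i}" for i in range(cfg.ordinal_levels))
        columns[f"ord{j + 1}"] = np.array([levels[c] for c in codes])
        kinds[f"ord{j + 1}"] = "ordinal"
        ordinal_levels[f"ord{j + 1}"] = levels

    ids = [f"S{i + 1:04d}" for i in range(n)]
    clinical = ClinicalTable(pd.DataFrame(columns, index=pd.Index(ids, name="sample")),
                             ClinicalSchema(kinds, ordinal_levels))

    # --- molecular block ----------------------------------------------------
    half_m = 0.5 * cfg.molecular_effect
    p, p_sig = cfg.n_molecular, cfg.n_molecular_signal
    mol = cfg.molecular_noise * rng.standard_normal((n, p))
    if p_sig:
        latent_cols = z[:, np.arange(p_sig) % q]
        mol[:, :p_sig] = (half_m * s_mol[:, None]
                          + a * latent_cols
                          + b * cfg.molecular_noise * rng.standard_normal((n, p_sig)))
        for tag, offset in mol_offsets.items():
            rows = np.array([t == tag for t in tags])
            mol[np.ix_(rows, np.arange(p_sig))] += offset
    features = [f"gene{j + 1:05d}" for j in range(p)]
    molecular = MolecularMatrix(pd.DataFrame(mol, index=ids, columns=features))

    labels = pd.Series(y.astype(str), index=pd.Index(ids, name="sample"))
    dataset = LabeledDataset(clinical, molecular, labels)
    annotations = pd.DataFrame({"label": y, "subgroup": tags},
                               index=pd.Index(ids, name="sample"))
    return dataset, annotations


def scenario_presets(n_samples: int = 120, n_molecular: int = 300,
                     seed: int = 0) -> dict[str, GeneratorConfig]:
    """Three canonical study conditions.

    * ``A`` -- the molecular classifier outperforms the clinical one: modest
      clinical separation, a fifth of each class planted in a clinically
      misleading cluster, clean molecular signal.
    * ``B`` -- the two spaces perform about equally well.
    * ``C`` -- the clinical classifier is the stronger one: strong clinical
      separation, weak molecular signal plus molecularly misleading clusters.
    """
    common = dict(n_samples=n_samples, n_molecular=n_molecular,
                  n_molecular_signal=max(10, n_molecular // 10), rho=0.3, seed=seed)
    return {
        "A": GeneratorConfig(
            clinical_effect=1.4, molecular_effect=1.0,
            subgroups=(SubgroupSpec(1, 0.2, "clinical"),), **common),
        "B": GeneratorConfig(
            clinical_effect=1.1, molecular_effect=1.0, subgroups=(), **common),
        "C": GeneratorConfig(
            clinical_effect=1.8, molecular_effect=0.5,
            subgroups=(SubgroupSpec(1, 0.2, "molecular"),), **common),
    }
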