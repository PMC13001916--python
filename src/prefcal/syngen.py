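"""Synthetic scenario generator and stakeholder endorsement streams.

Each case has a latent binary adherence outcome and two fixed-length
real-valued embeddings of the same scenario — a community-facing view and a
physician-facing view.  The embeddings are drawn from a latent-factor
Gaussian emulator: a per-stream unit signal direction scaled by ``snr`` plus
isotropic unit-variance noise whose components are correlated across the two
streams by ``cross_corr``.  Two endorsement streams are layered on top:

* community labels — one per case, equal to the underlying binary outcome
  flipped independently with probability ``sigma_comm``;
* physician labels — available only for a per-batch queried subset of
  ``k_queries`` cases, forced to "adherence" (1) with probability
  ``beta_phys`` regardless of the underlying outcome.

All randomness flows through explicit seeds / ``numpy.random.Generator``
instances; identical seeds reproduce identical output bitwise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError

FORMAT_VERSION = 1

#: Signal-to-noise ratio of the default generator.  Calibrated once so that,
#: with noise-free community feedback and bias-free physician feedback, the
#: training-batch endorsement-agreement reward plateaus near 0.90; frozen
#: thereafter.  See docs/methods.md.
DEFAULT_SNR = 1.8


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the scenario emulator.

    ``y_lo``/``y_hi`` are the two-point true-outcome levels; ``base_rate``
    is the probability of the high-adherence level.  ``snr`` scales the
    class-separating signal direction relative to unit isotropic noise;
    ``cross_corr`` correlates the community- and physician-stream noise
    componentwise.
    """

    n_cases: int = 10_000
    embed_dim: int = 64
    y_lo: float = 0.1
    y_hi: float = 0.9
    base_rate: float = 0.5
    snr: float = DEFAULT_SNR
    cross_corr: float = 0.5
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.n_cases, (int, np.integer)) and self.n_cases >= 2):
            raise ConfigError(f"n_cases must be an integer >= 2, got {self.n_cases!r}")
        if not (isinstance(self.embed_dim, (int, np.integer)) and self.embed_dim >= 2):
            raise ConfigError(f"embed_dim must be an integer >= 2, got {self.embed_dim!r}")
        if not 0.0 <= self.y_lo < 0.5:
            raise ConfigError(f"y_lo must lie in [0, 0.5), got {self.y_lo!r}")
        if not 0.5 < self.y_hi <= 1.0:
            raise ConfigError(f"y_hi must lie in (0.5, 1], got {self.y_hi!r}")
        if not 0.0 <= self.base_rate <= 1.0:
            raise ConfigError(f"base_rate must lie in [0, 1], got {self.base_rate!r}")
        if self.snr < 0:
            raise ConfigError(f"snr must be nonnegative, got {self.snr!r}")
        if not -1.0 <= self.cross_corr <= 1.0:
            raise ConfigError(f"cross_corr must lie in [-1, 1], got {self.cross_corr!r}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigError(
                f"test_fraction must lie in (0, 1), got {self.test_fraction!r}"
            )


@dataclass(frozen=True)
class FeedbackParams:
    """Degradation parameters of the two endorsement streams."""

    sigma_comm: float = 0.0
    beta_phys: float = 0.0
    k_queries: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.sigma_comm <= 1.0:
            raise ConfigError(f"sigma_comm must lie in [0, 1], got {self.sigma_comm!r}")
        if not 0.0 <= self.beta_phys <= 1.0:
            raise ConfigError(f"beta_phys must lie in [0, 1], got {self.beta_phys!r}")
        if not (isinstance(self.k_queries, (int, np.integer)) and self.k_queries >= 1):
            raise ConfigError(
                f"k_queries must be a positive integer, got {self.k_queries!r}"
            )


@dataclass
class ScenarioSet:
    """A generated set of cases with paired embeddings and a train/test split.

    ``outcomes`` holds the true target outcome y in [0, 1]; ``labels`` the
    underlying binary outcome z = 1[y >= 0.5]; ``split`` is a string array of
    "train"/"test".
    """

    outcomes: np.ndarray
    labels: np.ndarray
    comm_embed: np.ndarray
    phys_embed: np.ndarray
    split: np.ndarray
    provenance: GeneratorConfig = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.outcomes)

    @property
    def train_idx(self) -> np.ndarray:
        return np.flatnonzero(self.split == "train")

    @property
    def test_idx(self) -> np.ndarray:
        return np.flatnonzero(self.split == "test")

    def validate(self) -> None:
        n = self.n
        for name in ("labels", "comm_embed", "phys_embed", "split"):
            if len(getattr(self, name)) != n:
                raise IntegrityError(f"field {name} has wrong length (expected {n})")
        if not np.array_equal(self.labels, (self.outcomes >= 0.5).astype(np.int64)):
            raise IntegrityError("labels are not the 0.5-threshold binarization of outcomes")
        if not (np.isfinite(self.comm_embed).all() and np.isfinite(self.phys_embed).all()):
            raise IntegrityError("embeddings contain non-finite values")


def generate_scenarios(cfg: GeneratorConfig) -> ScenarioSet:
    """Draw a :class:`ScenarioSet` deterministically from ``cfg.seed``.

    Per case i: z_i ~ Bernoulli(base_rate), y_i = y_hi if z_i else y_lo, and
    each stream's embedding is (2 z_i - 1) * snr * u + eps with u a fixed
    per-stream unit direction and eps unit-variance isotropic noise whose
    components are correlated ``cross_corr`` across the two streams.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_cases, cfg.embed_dim

    u_c = rng.normal(size=d)
    u_c /= np.linalg.norm(u_c)
    u_p = rng.normal(size=d)
    u_p /= np.linalg.norm(u_p)

    z = (rng.random(n) < cfg.base_rate).astype(np.int64)
    y = np.where(z == 1, cfg.y_hi, cfg.y_lo)
    sign = (2 * z - 1).astype(np.float64)

    rho = cfg.cross_corr
    g1 = rng.normal(size=(n, d))
    g2 = rng.normal(size=(n, d))
    eps_c = g1
    eps_p = rho * g1 + np.sqrt(1.0 - rho * rho) * g2

    comm = sign[:, None] * cfg.snr * u_c[None, :] + eps_c
    phys = sign[:, None] * cfg.snr * u_p[None, :] + eps_p

    n_test = int(round(cfg.test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    perm = rng.permutation(n)
    split = np.full(n, "train", dtype=object)
    split[perm[:n_test]] = "test"
    split = split.astype(str)

    out = ScenarioSet(outcomes=y, labels=z, comm_embed=comm, phys_embed=phys,
                      split=split, provenance=cfg)
    out.validate()
    return out


def draw_community_labels(sset: ScenarioSet, sigma_comm: float,
                          rng: np.random.Generator) -> np.ndarray:
    """One community label per case: the binary outcome flipped w.p. sigma_comm."""
    if not 0.0 <= sigma_comm <= 1.0:
        raise ConfigError(f"sigma_comm must lie in [0, 1], got {sigma_comm!r}")
    flips = (rng.random(sset.n) < sigma_comm).astype(np.int64)
    return sset.labels ^ flips


def query_physician(batch_indices: np.ndarray, k: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Uniformly sample exactly k distinct case indices from the batch."""
    batch_indices = np.asarray(batch_indices)
    if k > len(batch_indices):
        raise ConfigError(
            f"k_queries={k} exceeds batch size {len(batch_indices)}"
        )
    return rng.choice(batch_indices, size=k, replace=False)


def draw_physician_labels(z_queried: np.ndarray, beta_phys: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Physician labels for queried cases: forced to 1 w.p. beta_phys, else z."""
    if not 0.0 <= beta_phys <= 1.0:
        raise ConfigError(f"beta_phys must lie in [0, 1], got {beta_phys!r}")
    z_queried = np.asarray(z_queried)
    forced = rng.random(len(z_queried)) < beta_phys
    return np.where(forced, 1, z_queried).astype(np.int64)


# ---------------------------------------------------------------------------
# Persistence: one CSV per matrix + a JSON sidecar with config and shapes.

def save_scenarios(sset: ScenarioSet, path: str | Path) -> None:
    """Write a scenario set to ``path`` (a directory, created if absent).

    Layout: cases.csv (case_id, outcome, label, split), comm_embed.csv,
    phys_embed.csv (case_id + e0..e{d-1}, %.17g so float64 round-trips
    exactly), meta.json (format version + GeneratorConfig incl. seed).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    sset.validate()
    n, d = sset.comm_embed.shape

    cases = pd.DataFrame({
        "case_id": np.arange(n),
        "outcome": sset.outcomes,
        "label": sset.labels,
        "split": sset.split,
    })
    cases.to_csv(path / "cases.csv", index=False, float_format="%.17g")

    header = "case_id," + ",".join(f"e{j}" for j in range(d))
    fmt = ["%d"] + ["%.17g"] * d
    for name, mat in (("comm_embed", sset.comm_embed), ("phys_embed", sset.phys_embed)):
        body = np.column_stack([np.arange(n), mat])
        np.savetxt(path / f"{name}.csv", body, fmt=fmt, delimiter=",",
                   header=header, comments="")

    meta = {
        "format_version": FORMAT_VERSION,
        "n_rows": int(n),
        "embed_dim": int(d),
        "config": dataclasses.asdict(sset.provenance),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_scenarios(path: str | Path) -> ScenarioSet:
    """Inverse of :func:`save_scenarios`; raises on tampered metadata."""
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise FileNotFoundError(f"no meta.json under {path}")
    try:
        meta = json.loads(meta_file.read_text())
    except json.JSONDecodeError as exc:
        raise IntegrityError(f"meta.json is not valid JSON: {exc}") from exc
    for key in ("format_version", "n_rows", "embed_dim", "config"):
        if key not in meta:
            raise IntegrityError(f"meta.json missing field {key!r}")
    if meta["format_version"] != FORMAT_VERSION:
        raise IntegrityError(
            f"unsupported format_version {meta['format_version']!r}"
        )
    cfg = GeneratorConfig(**meta["config"])

    cases = pd.read_csv(path / "cases.csv")
    mats = {}
    for name in ("comm_embed", "phys_embed"):
        body = np.loadtxt(path / f"{name}.csv", delimiter=",", skiprows=1, ndmin=2)
        mats[name] = body[:, 1:]

    n, d = meta["n_rows"], meta["embed_dim"]
    if len(cases) != n:
        raise IntegrityError(
            f"cases.csv has {len(cases)} rows but meta.json declares {n}"
        )
    for name, mat in mats.items():
        if mat.shape != (n, d):
            raise IntegrityError(
                f"{name}.csv has shape {mat.shape} but meta.json declares {(n, d)}"
            )

    out = ScenarioSet(
        outcomes=cases["outcome"].to_numpy(dtype=np.float64),
        labels=cases["label"].to_numpy(dtype=np.int64),
        comm_embed=mats["comm_embed"],
        phys_embed=mats["phys_embed"],
        split=cases["split"].to_numpy(dtype=str),
        provenance=cfg,
    )
    out.validate()
    return out
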