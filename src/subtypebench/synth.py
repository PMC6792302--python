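"""Synthetic multi-omics cohorts with planted subtypes.

Generates the study conditions every downstream stage is tested on:
several omics layers sharing one patient cohort, Gaussian block structure
with a controllable mean shift between subtypes, per-layer noise scales,
uniformly injected missing values, and subtype-dependent exponential
survival with independent exponential censoring.

The generator is deliberately simple — Gaussian marginals, feature-wise
independent noise — because its job is to provide cohorts whose ground
truth is known exactly, not to imitate the marginal distributions of real
sequencing or methylation data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .layers import OmicsLayer, ValidationError

__all__ = [
    "LayerSpec",
    "SyntheticSpec",
    "SyntheticCohort",
    "generate_cohort",
    "inject_missing",
    "write_cohort",
    "write_survival",
    "write_labels",
]


@dataclass(frozen=True)
class LayerSpec:
    """Shape and signal strength of one synthetic omics layer.

    ``separation`` is the magnitude of the subtype mean shift in units of
    the noise standard deviation; 0 means the layer carries no subtype
    signal at all.
    """

    name: str
    n_features: int
    separation: float = 5.0
    noise_sd: float = 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort.

    Defaults describe a moderately sized, clearly structured cohort:
    60 patients in 3 subtypes measured on two layers (a 100-feature
    "mrna" layer and an 80-feature "methylation" layer), separation 5,
    no missing values, and exponential event rates that differ an order
    of magnitude between the extreme subtypes with light censoring.
    """

    n_samples: int = 60
    n_subtypes: int = 3
    layer_specs: tuple[LayerSpec, ...] = (
        LayerSpec("mrna", 100),
        LayerSpec("methylation", 80),
    )
    missing_rate: float = 0.0
    survival_hazards: tuple[float, ...] = (0.02, 0.08, 0.2)
    censor_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_subtypes < 2:
            raise ValidationError("n_subtypes must be >= 2")
        if self.n_samples < 2 * self.n_subtypes:
            raise ValidationError("n_samples must be >= 2 * n_subtypes")
        if not self.layer_specs:
            raise ValidationError("at least one layer spec is required")
        for ls in self.layer_specs:
            if ls.n_features < 1:
                raise ValidationError(f"layer {ls.name!r}: n_features must be >= 1")
            if ls.separation < 0:
                raise ValidationError(f"layer {ls.name!r}: separation must be >= 0")
            if ls.noise_sd <= 0:
                raise ValidationError(f"layer {ls.name!r}: noise_sd must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if len(self.survival_hazards) != self.n_subtypes:
            raise ValidationError(
                "survival_hazards must have one rate per subtype "
                f"({len(self.survival_hazards)} given, {self.n_subtypes} subtypes)"
            )
        if any(h <= 0 for h in self.survival_hazards):
            raise ValidationError("survival hazards must be positive")
        if self.censor_rate <= 0:
            raise ValidationError("censor_rate must be positive")


@dataclass
class SyntheticCohort:
    """Generated cohort: omics layers, planted labels and survival."""

    layers: list[OmicsLayer]
    true_labels: np.ndarray  # subtype id per sample, 1..n_subtypes
    survival: pd.DataFrame = field(repr=False)  # columns: sample, time, event

    @property
    def sample_ids(self) -> list[str]:
        return self.layers[0].sample_ids


def _subtype_assignment(n_samples: int, n_subtypes: int) -> np.ndarray:
    """Sizes as equal as possible, remainder going to the lowest-index subtypes."""
    base, rem = divmod(n_samples, n_subtypes)
    sizes = [base + (1 if g < rem else 0) for g in range(n_subtypes)]
    return np.repeat(np.arange(1, n_subtypes + 1), sizes)


def generate_cohort(spec: SyntheticSpec) -> SyntheticCohort:
    """Generate a multi-omics cohort with planted subtype structure.

    For each layer, subtype ``g``'s samples are drawn feature-wise from
    ``Normal(mu_gf, noise_sd)`` where the offset ``mu_gf`` equals
    ``separation * noise_sd * r`` with ``r`` drawn once per
    (subtype, feature) uniformly from {-1, 0, +1}.  Event times are
    exponential at the subtype's hazard, censoring times exponential at
    ``censor_rate``; the observed time is the minimum and the event flag
    records whether the event came first.  Fully reproducible from
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = _subtype_assignment(spec.n_samples, spec.n_subtypes)
    width = max(3, len(str(spec.n_samples)))
    sample_ids = [f"S{j + 1:0{width}d}" for j in range(spec.n_samples)]

    layers: list[OmicsLayer] = []
    for ls in spec.layer_specs:
        # one offset sign per (subtype, feature), fixed across samples
        r = rng.integers(-1, 2, size=(spec.n_subtypes, ls.n_features))
        means = ls.separation * ls.noise_sd * r  # (n_subtypes, n_features)
        noise = rng.normal(0.0, ls.noise_sd, size=(ls.n_features, spec.n_samples))
        values = means[labels - 1, :].T + noise
        layer = OmicsLayer(
            name=ls.name,
            feature_ids=[f"{ls.name}_f{i + 1}" for i in range(ls.n_features)],
            sample_ids=sample_ids,
            values=values,
        )
        if spec.missing_rate > 0:
            layer = inject_missing(
                layer, spec.missing_rate, seed=int(rng.integers(0, 2**31 - 1))
            )
        layers.append(layer)

    hazards = np.asarray(spec.survival_hazards, dtype=float)
    event_time = rng.exponential(1.0 / hazards[labels - 1])
    censor_time = rng.exponential(1.0 / spec.censor_rate, size=spec.n_samples)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    survival = pd.DataFrame(
        {"sample": sample_ids, "time": time, "event": event}
    )
    return SyntheticCohort(layers=layers, true_labels=labels, survival=survival)


def inject_missing(layer: OmicsLayer, rate: float, seed: int) -> OmicsLayer:
    """Set exactly ``round(rate * n_entries)`` entries of a copy to NaN.

    Positions are drawn without replacement, reproducibly from ``seed``.
    """
    if not 0 <= rate < 1:
        raise ValidationError("missing rate must be in [0, 1)")
    out = layer.copy()
    n_entries = out.values.size
    n_missing = int(round(rate * n_entries))
    if n_missing == 0:
        return out
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_entries, size=n_missing, replace=False)
    out.values.flat[flat] = np.nan
    return out


def write_survival(survival: pd.DataFrame, path: str | Path) -> Path:
    """Write a survival table as 3-column TSV (sample, time, event)."""
    path = Path(path)
    survival[["sample", "time", "event"]].to_csv(path, sep="\t", index=False)
    return path


def write_labels(sample_ids: list[str], labels, path: str | Path) -> Path:
    """Write subtype labels as 2-column TSV (sample, subtype)."""
    path = Path(path)
    pd.DataFrame({"sample": sample_ids, "subtype": np.asarray(labels)}).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write all cohort files (layers, survival, labels) into ``out_dir``."""
    from .layers import write_layer

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for layer in cohort.layers:
        paths[layer.name] = write_layer(layer, out_dir / f"{layer.name}.tsv")
    paths["survival"] = write_survival(cohort.survival, out_dir / "survival.tsv")
    paths["labels"] = write_labels(
        cohort.sample_ids, cohort.true_labels, out_dir / "true_labels.tsv"
    )
    return paths
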