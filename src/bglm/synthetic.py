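"""Synthetic lab-event scenario generator with known ground truth.

Emulates the statistical structure the distribution mapper assumes: a
reference table keyed by LOINC code (a MIMIC-style LABEVENTS extract) and a
query table keyed by opaque local codes, linked only through a truth table.
Distribution families mimic common quantitative analytes — normal
(electrolytes), lognormal (enzymes), gamma (skewed markers), uniform, and
a Poisson "discrete" family whose integer values exercise tie handling in
the KS scan. Controls:

* ``query_shift`` — per-code additive location / multiplicative scale
  perturbation of the query values, modeling cross-site assay differences;
* ``confuser_pairs`` — pairs of LOINC codes forced to near-identical
  parameters, creating genuinely ambiguous candidates;
* ``unmapped_fraction`` — proportion of query codes whose true LOINC is
  withheld from the reference panel, producing the necessarily-wrong
  mappings the Z-score cutoff must reject.

Everything is reproducible from the scenario seed; each code draws from an
independently derived sub-stream so adding a code never perturbs others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .ecdf import derive_subseed
from .exceptions import ConfigError
from .io_tables import LabEventTable, TruthTable

_FAMILIES = ("normal", "lognormal", "gamma", "uniform", "discrete", "mixture")


@dataclass(frozen=True)
class CodeSpec:
    """One lab code's generating distribution and per-table sample counts."""

    loinc: str
    family: str
    params: tuple[float, ...]
    n_reference: int = 5000
    n_query: int = 5000

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        if self.n_reference < 1 or self.n_query < 1:
            raise ConfigError("sample counts must be positive")
        _validate_params(self.family, self.params)

    def nominal_moments(self) -> tuple[float, float]:
        """(mean, sd) of the generating distribution, used to scale shifts."""
        p = self.params
        if self.family == "normal":
            return p[0], p[1]
        if self.family == "lognormal":
            mean = math.exp(p[0] + p[1] ** 2 / 2)
            return mean, mean * math.sqrt(math.expm1(p[1] ** 2))
        if self.family == "gamma":
            return p[0] * p[1], math.sqrt(p[0]) * p[1]
        if self.family == "uniform":
            return (p[0] + p[1]) / 2, (p[1] - p[0]) / math.sqrt(12)
        if self.family == "mixture":
            loc, sd, w, bg_loc, bg_sd = p
            mean = w * loc + (1 - w) * bg_loc
            second = w * (sd**2 + loc**2) + (1 - w) * (bg_sd**2 + bg_loc**2)
            return mean, math.sqrt(second - mean**2)
        return p[0], math.sqrt(p[0])  # discrete (Poisson)

    def shift_scale(self) -> float:
        """Scale used to calibrate "mild" query shifts.

        For the mixture family the code-specific component's sd is the
        meaningful assay scale (the shared background is common to every
        code); elsewhere it is the distribution's own sd.
        """
        if self.family == "mixture":
            return self.params[1]
        return self.nominal_moments()[1]

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "normal":
            return rng.normal(p[0], p[1], size=n)
        if self.family == "lognormal":
            return rng.lognormal(p[0], p[1], size=n)
        if self.family == "gamma":
            return rng.gamma(p[0], p[1], size=n)
        if self.family == "uniform":
            return rng.uniform(p[0], p[1], size=n)
        if self.family == "mixture":
            loc, sd, w, bg_loc, bg_sd = p
            unique = rng.normal(loc, sd, size=n)
            background = rng.normal(bg_loc, bg_sd, size=n)
            return np.where(rng.random(n) < w, unique, background)
        return rng.poisson(p[0], size=n).astype(float)


def _validate_params(family: str, params: tuple[float, ...]) -> None:
    try:
        if family == "normal" and not (len(params) == 2 and params[1] > 0):
            raise ConfigError("normal needs (mean, sd>0)")
        if family == "lognormal" and not (len(params) == 2 and params[1] > 0):
            raise ConfigError("lognormal needs (log-mean, log-sd>0)")
        if family == "gamma" and not (len(params) == 2 and params[0] > 0 and params[1] > 0):
            raise ConfigError("gamma needs (shape>0, scale>0)")
        if family == "uniform" and not (len(params) == 2 and params[1] > params[0]):
            raise ConfigError("uniform needs (low, high>low)")
        if family == "discrete" and not (len(params) == 1 and params[0] > 0):
            raise ConfigError("discrete needs (rate>0)")
        if family == "mixture" and not (
            len(params) == 5 and params[1] > 0 and 0 < params[2] <= 1 and params[4] > 0
        ):
            raise ConfigError("mixture needs (loc, sd>0, weight in (0,1], bg_loc, bg_sd>0)")
    except (TypeError, IndexError) as exc:
        raise ConfigError(f"invalid params {params!r} for family {family!r}") from exc


@dataclass
class ScenarioConfig:
    """Full description of a synthetic query/reference/truth scenario."""

    specs: list[CodeSpec]
    query_shift: dict[str, tuple[float, float]] = field(default_factory=dict)
    confuser_pairs: list[tuple[str, str]] = field(default_factory=list)
    unmapped_fraction: float = 0.0
    seed: int = 0
    reference_only: list[str] = field(default_factory=list)
    """LOINC codes present in the reference panel but never queried.

    A real reference (a MIMIC-style extract) carries far more LOINC codes
    than any one institution queries; these widen the candidate panel K.
    The Z-score of a row of length K is bounded below by -(K-1)/sqrt(K),
    so stringent cutoffs such as -5 are only meaningful for K of about 30
    or more — matching the wide-panel regime the method targets.
    """

    def __post_init__(self) -> None:
        if not self.specs:
            raise ConfigError("scenario needs at least one code spec")
        if not (0 <= self.unmapped_fraction < 1):
            raise ConfigError("unmapped_fraction must be in [0, 1)")
        loincs = [s.loinc for s in self.specs]
        if len(set(loincs)) != len(loincs):
            raise ConfigError("duplicate LOINC codes in scenario specs")
        if not set(self.reference_only) <= set(loincs):
            raise ConfigError("reference_only lists unknown LOINC codes")
        if set(self.reference_only) == set(loincs):
            raise ConfigError("at least one code must appear in the query")


def _apply_confusers(config: ScenarioConfig) -> list[CodeSpec]:
    """Copy each confuser pair's first spec onto the second, nudged slightly."""
    by_loinc = {s.loinc: s for s in config.specs}
    for a, b in config.confuser_pairs:
        if a not in by_loinc or b not in by_loinc:
            raise ConfigError(f"confuser pair ({a}, {b}) references unknown LOINC")
        src = by_loinc[a]
        _, sd = src.nominal_moments()
        params = list(src.params)
        params[0] = params[0] + 0.01 * sd  # near-identical, not byte-identical
        by_loinc[b] = replace(src, loinc=b, params=tuple(params))
    return [by_loinc[s.loinc] for s in config.specs]


def generate_scenario(
    config: ScenarioConfig,
) -> tuple[LabEventTable, LabEventTable, TruthTable]:
    """Materialize a scenario into (query, reference, truth) tables.

    Local code ids are opaque strings ("Q0000", ...) linked to LOINC codes
    only through the truth table. Codes selected by ``unmapped_fraction``
    appear in the query and the truth but their LOINC is withheld from the
    reference panel.
    """
    specs = _apply_confusers(config)
    ref_only = set(config.reference_only)
    queried = [s for s in specs if s.loinc not in ref_only]
    n_unmapped = int(round(config.unmapped_fraction * len(queried)))
    withheld: set[str] = set()
    if n_unmapped:
        pick_rng = np.random.default_rng(derive_subseed(config.seed, "unmapped-pick"))
        picked = pick_rng.choice(len(queried), size=n_unmapped, replace=False)
        withheld = {queried[i].loinc for i in picked}

    ref_rows: list[tuple[str, float]] = []
    query_rows: list[tuple[str, float]] = []
    truth: dict[str, str] = {}
    for spec in specs:
        if spec.loinc not in withheld:
            ref_rng = np.random.default_rng(derive_subseed(config.seed, f"ref:{spec.loinc}"))
            ref_rows.extend((spec.loinc, v) for v in spec.draw(spec.n_reference, ref_rng))
    for i, spec in enumerate(queried):
        local_id = f"Q{i:04d}"
        truth[local_id] = spec.loinc
        qry_rng = np.random.default_rng(derive_subseed(config.seed, f"query:{local_id}"))
        values = spec.draw(spec.n_query, qry_rng)
        loc_add, scale_mult = config.query_shift.get(spec.loinc, (0.0, 1.0))
        query_rows.extend((local_id, v) for v in values * scale_mult + loc_add)

    if not ref_rows:
        raise ConfigError("unmapped_fraction left the reference panel empty")
    return (
        LabEventTable.from_records(query_rows, source_label="query"),
        LabEventTable.from_records(ref_rows, source_label="reference"),
        TruthTable(truth=truth),
    )


def make_confusable_panel(
    k: int, overlap: float, seed: int = 0, n_reference_only: int = 0
) -> ScenarioConfig:
    """Panel of *k* unit-variance normal codes with tunable pairwise overlap.

    Adjacent locations are separated by ``6 * (1 - overlap)`` standard
    deviations: at ``overlap=0`` distinct codes are essentially disjoint in
    distribution (pairwise KS near 1), at ``overlap=1`` all codes share
    identical parameters. ``n_reference_only`` appends further codes on the
    same location grid that appear only in the reference panel, emulating a
    reference far wider than any one site's query set.
    """
    if k < 2:
        raise ConfigError("panel needs k >= 2")
    if not (0 <= overlap <= 1):
        raise ConfigError("overlap must be in [0, 1]")
    sep = 6.0 * (1.0 - overlap)
    total = k + n_reference_only
    specs = [
        CodeSpec(loinc=f"{10000 + i}-1", family="normal", params=(i * sep, 1.0))
        for i in range(total)
    ]
    return ScenarioConfig(
        specs=specs,
        seed=seed,
        reference_only=[s.loinc for s in specs[k:]],
    )


def make_analyte_panel(
    n_query: int,
    n_reference_only: int = 20,
    seed: int = 0,
    weight_range: tuple[float, float] = (0.65, 0.85),
    spacing: float = 6.0,
    background_sd: float = 50.0,
    unmapped_fraction: float = 0.0,
) -> ScenarioConfig:
    """Panel emulating analytes that share part of their dynamic range.

    Each code draws a fraction *w* (the mixture weight, varied per code
    within ``weight_range``) from a code-specific normal component on a
    shuffled location grid, and the rest from one broad background common
    to every code. The shared background cancels in any pairwise KS
    comparison, so inter-code distances sit in a tight bulk near *w*
    instead of saturating at 1 — the regime where the Z-score of the best
    match is informative. A true match is then a strong row outlier (very
    negative Z) while the best available match for a code missing from the
    reference falls inside the bulk's lower tail (moderate Z), which is
    exactly the contrast the cutoff exploits. ``n_reference_only`` extra
    codes widen the candidate panel the way a MIMIC-style reference dwarfs
    any one site's query set.
    """
    if n_query < 2:
        raise ConfigError("panel needs n_query >= 2")
    total = n_query + n_reference_only
    rng = np.random.default_rng(derive_subseed(seed, "analyte-panel"))
    locations = rng.permutation(total) * spacing
    weights = rng.uniform(*weight_range, size=total)
    bg_loc = spacing * total / 2
    specs = [
        CodeSpec(
            loinc=f"{10000 + i}-1",
            family="mixture",
            params=(float(locations[i]), 1.0, float(weights[i]), bg_loc, background_sd),
        )
        for i in range(total)
    ]
    return ScenarioConfig(
        specs=specs,
        seed=seed,
        unmapped_fraction=unmapped_fraction,
        reference_only=[s.loinc for s in specs[n_query:]],
    )


def make_mixed_panel(seed: int = 0) -> ScenarioConfig:
    """Small well-separated panel covering all five distribution families."""
    specs = [
        CodeSpec("2951-2", "normal", (140.0, 3.0)),      # sodium-like, mmol/L
        CodeSpec("1742-6", "lognormal", (3.2, 0.5)),     # ALT-like, U/L
        CodeSpec("1988-5", "gamma", (2.0, 4.0)),         # CRP-like, mg/L
        CodeSpec("2345-7", "uniform", (350.0, 450.0)),
        CodeSpec("6690-2", "discrete", (9.0,)),          # WBC-like integer counts
    ]
    return ScenarioConfig(specs=specs, seed=seed)


def add_mild_shift(
    config: ScenarioConfig,
    location_frac: float = 0.05,
    scale_jitter: float = 0.02,
    seed: int | None = None,
) -> ScenarioConfig:
    """Return a copy with per-code query shifts drawn within mild bounds.

    Each code gets an additive location shift uniform in +/- ``location_frac``
    of its reference sd and a scale factor uniform in 1 +/- ``scale_jitter``,
    modeling cross-site assay differences without breaking identifiability.
    """
    rng = np.random.default_rng(
        derive_subseed(config.seed if seed is None else seed, "query-shift")
    )
    shift = {}
    for spec in config.specs:
        sd = spec.shift_scale()
        shift[spec.loinc] = (
            float(rng.uniform(-location_frac, location_frac) * sd),
            float(1.0 + rng.uniform(-scale_jitter, scale_jitter)),
        )
    return replace(config, query_shift=shift)


def scenario_to_yaml(config: ScenarioConfig, path) -> None:
    data = {
        "seed": config.seed,
        "unmapped_fraction": config.unmapped_fraction,
        "reference_only": list(config.reference_only),
        "confuser_pairs": [list(p) for p in config.confuser_pairs],
        "query_shift": {k: list(v) for k, v in config.query_shift.items()},
        "specs": [
            {
                "loinc": s.loinc,
                "family": s.family,
                "params": list(s.params),
                "n_reference": s.n_reference,
                "n_query": s.n_query,
            }
            for s in config.specs
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def scenario_from_yaml(path) -> ScenarioConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    try:
        specs = [
            CodeSpec(
                loinc=str(s["loinc"]),
                family=s["family"],
                params=tuple(float(p) for p in s["params"]),
                n_reference=int(s.get("n_reference", 5000)),
                n_query=int(s.get("n_query", 5000)),
            )
            for s in data["specs"]
        ]
        return ScenarioConfig(
            specs=specs,
            query_shift={
                str(k): (float(v[0]), float(v[1]))
                for k, v in (data.get("query_shift") or {}).items()
            },
            confuser_pairs=[tuple(p) for p in (data.get("confuser_pairs") or [])],
            unmapped_fraction=float(data.get("unmapped_fraction", 0.0)),
            seed=int(data.get("seed", 0)),
            reference_only=[str(c) for c in (data.get("reference_only") or [])],
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid scenario file {path}: {exc}") from exc
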