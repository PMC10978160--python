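"""Synthetic monitoring-campaign generator.

Real wipe/glove campaigns from hospital preparation units are rarely
shareable, so every pipeline stage is exercised against generated data
with controllable statistical structure: each wipe or glove sample is
assayed for every analyte on the campaign panel (as a multi-analyte
LC-MS/MS method would), each (sample, analyte) result is positive with
a configurable probability, and positive loads are drawn from a
lognormal distribution left-censored at the LOQ — the standard model
for surface-contamination data.

:func:`spec_for_target_rpns` inverts the scoring rubric: given a target
RPN for each of the five monitoring parameters it returns a campaign
spec whose expected summary lands in the interior of each target band,
so that downstream scoring recovers the intended profile with high
probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .arl import PrepMode
from .catalog import ADGroup
from .errors import ConfigError, UnsatisfiableTargetError
from .monitoring import (
    BELOW_LOQ_TOKEN,
    Medium,
    MonitoringCampaign,
    SampleRecord,
    ShiftPhase,
    SPREAD_STATS,
)
from .scoring import AGVConfig, BinTable, OrdinalBins

__all__ = [
    "CampaignSpec",
    "generate_campaign",
    "spec_for_target_rpns",
    "campaign_to_csv",
    "write_spec_sidecar",
]

_HOSPITALS = {PrepMode.MANUAL: ("H1", "H2"), PrepMode.AUTOMATED: ("H3", "H4")}
_LOCATIONS = {
    Medium.SURFACE: (
        "bsc_interior",
        "bsc_exterior",
        "floor",
        "pass_through",
        "storage_shelf",
    ),
    Medium.GLOVE: (
        "operator_left",
        "operator_right",
        "assistant_left",
        "assistant_right",
    ),
}

PerMedium = Union[float, Mapping[str, float]]


def _per_medium(value: PerMedium, medium: Medium, name: str) -> float:
    if isinstance(value, Mapping):
        try:
            return float(value[medium.value])
        except KeyError:
            raise ConfigError(f"{name}: missing entry for medium {medium.value!r}")
    return float(value)


@dataclass(frozen=True)
class CampaignSpec:
    """Parameters of one synthetic campaign stratum.

    ``detection_prob`` and ``log_mean`` accept either a scalar or a
    per-medium mapping ``{"surface": ..., "glove": ...}`` — surfaces
    and gloves are binned separately downstream, so a targeting spec
    usually needs different prevalences per medium.  ``log_mean`` /
    ``log_sd`` parameterise the natural-log scale of the lognormal load
    distribution (loads in pg/cm2).  ``location_sd`` adds a normal
    random intercept per sampling location on the log scale (default 0:
    per-record independence).
    """

    seed: int
    drugs: tuple[str, ...]
    n_surface_samples: int = 100
    n_glove_samples: int = 100
    detection_prob: PerMedium = 0.2
    log_mean: PerMedium = 3.0
    log_sd: PerMedium = 1.0
    loq: float = 0.1
    location_sd: float = 0.0
    prep_modes: tuple[PrepMode, ...] = (PrepMode.MANUAL,)
    group: Optional[ADGroup] = None

    def __post_init__(self) -> None:
        if not self.drugs:
            raise ConfigError("spec needs at least one drug")
        if self.n_surface_samples <= 0 or self.n_glove_samples <= 0:
            raise ConfigError("sample counts must be > 0")
        if not self.loq > 0:
            raise ConfigError("loq must be > 0")
        if self.location_sd < 0:
            raise ConfigError("location_sd must be >= 0")
        if not self.prep_modes:
            raise ConfigError("spec needs at least one preparation mode")
        for medium in Medium:
            p = _per_medium(self.detection_prob, medium, "detection_prob")
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"detection_prob must be in [0, 1], got {p}")
            if not _per_medium(self.log_sd, medium, "log_sd") > 0:
                raise ConfigError("log_sd must be > 0")

    def to_jsonable(self) -> dict:
        out = asdict(self)
        out["prep_modes"] = [m.value for m in self.prep_modes]
        out["group"] = self.group.value if self.group else None
        out["drugs"] = list(self.drugs)
        return out


def generate_campaign(spec: CampaignSpec) -> MonitoringCampaign:
    """Generate a reproducible campaign from a spec.

    Each of the ``n_*_samples`` wipes/gloves per preparation mode is
    assayed for every drug on the panel; results flagged positive get a
    lognormal load, then loads under the LOQ are censored.  Load draws
    do not depend on the LOQ, so re-generating with a higher LOQ only
    censors more records, never reshuffles them.  Both shift phases are
    emitted (samples alternate start/end).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SampleRecord] = []
    for mode in spec.prep_modes:
        hospitals = _HOSPITALS[mode]
        for medium, n_samples in (
            (Medium.SURFACE, spec.n_surface_samples),
            (Medium.GLOVE, spec.n_glove_samples),
        ):
            p = _per_medium(spec.detection_prob, medium, "detection_prob")
            mu = _per_medium(spec.log_mean, medium, "log_mean")
            sd = _per_medium(spec.log_sd, medium, "log_sd")
            locations = _LOCATIONS[medium]
            loc_effect = (
                rng.normal(0.0, spec.location_sd, size=len(locations))
                if spec.location_sd > 0
                else np.zeros(len(locations))
            )
            k = len(spec.drugs)
            flagged = rng.random((n_samples, k)) < p
            # Always draw loads so the stream is invariant to loq/p edits.
            loads = rng.lognormal(mu, sd, size=(n_samples, k))
            for i in range(n_samples):
                loc_idx = i % len(locations)
                shifted = loads[i] * float(np.exp(loc_effect[loc_idx]))
                for j, drug_id in enumerate(spec.drugs):
                    load: Optional[float]
                    if flagged[i, j] and shifted[j] >= spec.loq:
                        load = float(shifted[j])
                    else:
                        load = None
                    records.append(
                        SampleRecord(
                            sample_id=f"{mode.value[:3]}-{medium.value[:3]}-{i:05d}-{drug_id}",
                            hospital_id=hospitals[i % len(hospitals)],
                            prep_mode=mode,
                            medium=medium,
                            location=locations[loc_idx],
                            shift_phase=ShiftPhase.START if i % 2 == 0 else ShiftPhase.END,
                            drug_id=drug_id,
                            load=load,
                            loq=spec.loq,
                        )
                    )
    return MonitoringCampaign(
        records=records,
        metadata={"seed": spec.seed, "synthetic": True},
    )


def campaign_to_csv(campaign: MonitoringCampaign, path: Union[str, Path]) -> None:
    """Write a campaign in the samples-CSV schema (deterministic bytes)."""
    path = Path(path)
    lines = [
        "sample_id,hospital_id,prep_mode,medium,location,shift_phase,"
        "drug_id,load_pg_cm2,loq_pg_cm2"
    ]
    for r in campaign.records:
        load = BELOW_LOQ_TOKEN if r.load is None else f"{r.load:.6g}"
        lines.append(
            f"{r.sample_id},{r.hospital_id},{r.prep_mode.value},{r.medium.value},"
            f"{r.location},{r.shift_phase.value},{r.drug_id},{load},{r.loq:.6g}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_spec_sidecar(spec: CampaignSpec, path: Union[str, Path]) -> None:
    """Record the generating spec (including the seed) next to the CSV."""
    Path(path).write_text(
        json.dumps(spec.to_jsonable(), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


# --- Rubric inversion -------------------------------------------------

#: Detected-AD count targeted for each count-parameter RPN band
#: (band 4 covers counts 4-5, band 5 is >=6).
_COUNT_FOR_BAND = {1: 1, 2: 2, 3: 3, 4: 4, 5: 6}


def _pct_band_interior(bins: OrdinalBins, band: int) -> float:
    """Midpoint of a percentage band; open top band spans lo..1.5*lo."""
    lo = 0.0 if band == 1 else bins.edges[band - 2]
    hi = bins.edges[band - 1] if band <= 4 else min(100.0, 1.5 * bins.edges[3])
    return (lo + hi) / 2.0


def _spread_band_interior(bins: OrdinalBins, band: int, floor: float) -> float:
    """Geometric midpoint of a load band (loads live on a log scale)."""
    lo = floor if band == 1 else bins.edges[band - 2]
    hi = bins.edges[band - 1] if band <= 4 else 2.5 * bins.edges[3]
    return float(np.sqrt(lo * hi))


def spec_for_target_rpns(
    target: Sequence[int],
    bins: BinTable,
    agv: AGVConfig,
    *,
    drugs: Sequence[str],
    prep_mode: PrepMode = PrepMode.MANUAL,
    group: Optional[ADGroup] = None,
    n_surface_samples: int = 1000,
    n_glove_samples: int = 1000,
    log_sd: float = 0.3,
    spread_stat: str = "p90",
    seed: int = 0,
) -> CampaignSpec:
    """Build a spec whose expected summary hits a target RPN profile.

    ``target`` gives the intended RPN (1–5) for, in order: number of
    detected ADs, surface spread, % positive surfaces, glove spread,
    % positive gloves.  Percentage targets set the per-record detection
    probability to the band midpoint; spread targets set the lognormal
    log-mean so the configured spread quantile sits at the geometric
    band midpoint (``log_sd`` is kept tight so the realised quantile
    stays inside the band); the count target selects how many panel
    drugs are active.

    Raises
    ------
    UnsatisfiableTargetError
        If the count target needs more drugs than the panel offers, or
        if a below-LOQ glove-spread target is combined with a nonzero
        glove-percentage target (a positive glove implies a
        quantifiable load).
    """
    target = tuple(int(t) for t in target)
    if len(target) != 5 or any(not 1 <= t <= 5 for t in target):
        raise UnsatisfiableTargetError(
            f"target must be five RPNs in 1..5, got {target!r}"
        )
    t_count, t_sspread, t_spct, t_gspread, t_gpct = target
    agv_default = agv.resolve(None)
    loq = agv_default.loq
    glove_bins = agv_default.glove_bins()
    z = norm.ppf(SPREAD_STATS[spread_stat])

    if target == (1, 1, 1, 1, 1):
        return CampaignSpec(
            seed=seed,
            drugs=tuple(drugs[:1]),
            n_surface_samples=n_surface_samples,
            n_glove_samples=n_glove_samples,
            detection_prob=0.0,
            log_mean=np.log(loq),
            log_sd=log_sd,
            loq=loq,
            prep_modes=(prep_mode,),
            group=group,
        )

    n_active = _COUNT_FOR_BAND[t_count]
    if n_active > len(drugs):
        raise UnsatisfiableTargetError(
            f"count target {t_count} needs {n_active} drugs, panel has {len(drugs)}"
        )
    if t_gspread == 1 and t_gpct != 1:
        raise UnsatisfiableTargetError(
            "glove spread below LOQ is incompatible with a nonzero "
            "glove-percentage target"
        )

    p_surface = _pct_band_interior(bins.pct_surfaces, t_spct) / 100.0
    p_glove = (
        0.0
        if t_gspread == 1
        else _pct_band_interior(bins.pct_gloves, t_gpct) / 100.0
    )
    mu_surface = float(
        np.log(_spread_band_interior(bins.surface_spread, t_sspread, loq)) - z * log_sd
    )
    if t_gspread == 1:
        mu_glove = float(np.log(loq))
    else:
        mu_glove = float(
            np.log(_spread_band_interior(glove_bins, t_gspread, loq)) - z * log_sd
        )
    return CampaignSpec(
        seed=seed,
        drugs=tuple(drugs[:n_active]),
        n_surface_samples=n_surface_samples,
        n_glove_samples=n_glove_samples,
        detection_prob={"surface": p_surface, "glove": p_glove},
        log_mean={"surface": mu_surface, "glove": mu_glove},
        log_sd=log_sd,
        loq=loq,
        prep_modes=(prep_mode,),
        group=group,
    )
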