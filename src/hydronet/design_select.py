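"""Design filtering and ranking.

Applies three selection criteria to per-design computed properties:

1. conformational stability of the active versus the inactive state
   (ddG_apo; large positive values predict loss of signalling);
2. water-mediated hydrogen-bond connectivity between static and switchable
   helices (low counts predict loss of allosteric coupling);
3. strength of protein-ion interactions (a second-order tie-breaker).

Designs destabilised in BOTH states (dG_inactive and dG_active above the
unfold threshold) are discarded outright as likely unfolded; single-state
destabilisation is the design lever of criterion 1 and is allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import math

import pandas as pd

from .network import classify_hydration


@dataclass
class SelectionConfig:
    unfold_threshold: float = 8.0  # REU: both-state destabilisation cut
    c1_threshold: float = 5.0  # REU: ddG_apo above this flags activity loss
    c2_threshold: int = 18  # static-switchable count below this flags c2
    reference_count: int = 20  # reference receptor's static-switchable count


@dataclass
class DesignRecord:
    design_id: str
    dG_inactive: float
    dG_active: float
    ddG_apo: float
    n_static_switchable: int
    n_total_water_hb: int | None = None
    ion_dE: float | None = None  # REU, site - bulk
    mutations: list[tuple[str, str, str]] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)
    hydration_class: str | None = None
    discard_reason: str | None = None


def filter_unfolded(
    designs: list[DesignRecord], config: SelectionConfig | None = None
) -> tuple[list[DesignRecord], list[DesignRecord]]:
    """Discard designs destabilised in both conformational states.

    A design is discarded only when ``dG_inactive`` AND ``dG_active`` both
    exceed the unfold threshold; records with missing/non-finite energies are
    also discarded, with a reason.
    """
    config = config or SelectionConfig()
    retained, discarded = [], []
    for d in designs:
        if any(
            v is None or not math.isfinite(v) for v in (d.dG_inactive, d.dG_active)
        ):
            d.discard_reason = "missing or non-finite state energy"
            discarded.append(d)
            continue
        if d.dG_inactive > config.unfold_threshold and d.dG_active > config.unfold_threshold:
            d.flags.add("unfolded")
            d.discard_reason = (
                f"both states destabilised beyond {config.unfold_threshold} REU"
            )
            discarded.append(d)
        else:
            retained.append(d)
    return retained, discarded


def apply_criteria(
    designs: list[DesignRecord], config: SelectionConfig | None = None
) -> list[DesignRecord]:
    """Set criterion flags and the hydration class on retained designs."""
    config = config or SelectionConfig()
    for d in designs:
        if d.ddG_apo > config.c1_threshold:
            d.flags.add("c1_loss")
        if d.n_static_switchable < config.c2_threshold:
            d.flags.add("c2_fail")
        d.hydration_class = classify_hydration(d.n_static_switchable, config.reference_count)
    return designs


def rank_designs(
    designs: list[DesignRecord], config: SelectionConfig | None = None
) -> list[DesignRecord]:
    """Deterministic total order: unflagged designs first.

    Within each group: static-switchable connectivity descending, then
    ddG_apo ascending, then ion interaction energy ascending (missing values
    last), finally design id.  Permuting the input never changes the output.
    """
    def key(d: DesignRecord):
        ion = d.ion_dE if d.ion_dE is not None else math.inf
        return (
            1 if d.flags else 0,
            -d.n_static_switchable,
            d.ddG_apo,
            ion,
            d.design_id,
        )

    return sorted(designs, key=key)


def select(
    designs: list[DesignRecord], config: SelectionConfig | None = None
) -> tuple[list[DesignRecord], list[DesignRecord]]:
    """Full pipeline: unfold filter, criterion flags, deterministic ranking."""
    config = config or SelectionConfig()
    retained, discarded = filter_unfolded(designs, config)
    apply_criteria(retained, config)
    return rank_designs(retained, config), discarded


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

_COLUMNS = [
    "design_id", "dG_inactive", "dG_active", "ddG_apo",
    "n_static_switchable", "n_total_water_hb", "ion_dE",
]


def load_design_table(path) -> list[DesignRecord]:
    """Design TSV with columns matching :class:`DesignRecord` fields."""
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for r in df.itertuples(index=False):
        records.append(
            DesignRecord(
                design_id=str(r.design_id),
                dG_inactive=float(r.dG_inactive),
                dG_active=float(r.dG_active),
                ddG_apo=float(r.ddG_apo),
                n_static_switchable=int(r.n_static_switchable),
                n_total_water_hb=int(r.n_total_water_hb)
                if "n_total_water_hb" in df.columns and not pd.isna(r.n_total_water_hb)
                else None,
                ion_dE=float(r.ion_dE)
                if "ion_dE" in df.columns and not pd.isna(r.ion_dE)
                else None,
            )
        )
    return records


def write_ranked_table(
    ranked: list[DesignRecord], discarded: list[DesignRecord], path
) -> None:
    rows = []
    for rank, d in enumerate(ranked, start=1):
        rows.append(_row(d, rank=rank, status="retained"))
    for d in discarded:
        rows.append(_row(d, rank=None, status="discarded"))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _row(d: DesignRecord, rank, status):
    return {
        "rank": rank,
        "status": status,
        "design_id": d.design_id,
        "dG_inactive": d.dG_inactive,
        "dG_active": d.dG_active,
        "ddG_apo": d.ddG_apo,
        "n_static_switchable": d.n_static_switchable,
        "n_total_water_hb": d.n_total_water_hb,
        "ion_dE": d.ion_dE,
        "class": d.hydration_class,
        "flags": ",".join(sorted(d.flags)),
        "reason": d.discard_reason or "",
    }
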