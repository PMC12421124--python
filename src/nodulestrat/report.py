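"""End-to-end pipeline driver and table rendering.

``run_pipeline`` assembles the whole baseline analysis — cohort input
(file, generator or the packaged count-matched fixture), index reduction,
Brock scoring, rule-out and rule-in performance tables, and the weighted
net-benefit comparisons — into one machine-readable summary plus rendered
tables.  Rendering is a pure formatting function of the summary:
percentages at one decimal (half-up), CIs in parentheses, p-values at four
decimals with a "<0.0001" floor.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from . import __version__
from .accuracy import (
    crude_risk,
    diagnostic_summary,
    false_positive_reduction,
    mcnemar,
    pearson_chi2,
)
from .brock import brock_for_cohort
from .cohort import ProtocolConfig, load_cohort, reduce_to_index
from .errors import ConfigurationError
from .netbenefit import bootstrap_net_benefit
from .protocol import BrockGatedRule, SizeRule, stratify
from .synthetic import (
    FallbackRule,
    GeneratorParams,
    generate_cohort,
    marginal_counts,
    packaged_counts_spec,
    reconstruct_fixture,
)

__all__ = ["RunConfig", "run_pipeline", "render_table", "fmt_pct", "fmt_p"]

_ANALYSES = ("table1", "table2", "net_benefit")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration.  Cohort source precedence: an explicit file,
    else a generator parameter set, else the packaged count-matched
    fixture."""

    cohort_path: str | None = None
    layout: str = "participant_rows"
    generator: GeneratorParams | None = None
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    analyses: tuple[str, ...] = _ANALYSES
    out_dir: str | None = None
    seed: int = 0
    ci_level: float = 0.95
    n_bootstrap: int = 1000
    nb_weight_rule_out: float = 50.0
    nb_weight_rule_in: float = 5.0
    nb_prevalence_source: str = "nodule_participants"

    def validate(self) -> None:
        if not self.analyses:
            raise ConfigurationError("analyses must be non-empty")
        unknown = set(self.analyses) - set(_ANALYSES)
        if unknown:
            raise ConfigurationError(f"unknown analyses: {sorted(unknown)}")
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise ConfigurationError(f"cohort file not found: {self.cohort_path}")


def _round_half_up(x: float, places: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{places}"), ROUND_HALF_UP))


def fmt_pct(fraction_pct: float, places: int = 1) -> str:
    """Render a percentage at one decimal, half-up: 86.842 -> '86.8%'."""
    return f"{_round_half_up(fraction_pct, places):.{places}f}%"


def fmt_p(p: float) -> str:
    """Render a p-value at 4 decimals with a '<0.0001' floor."""
    if p < 0.0001:
        return "<0.0001"
    return f"{_round_half_up(p, 4):.4f}"


def _fmt_triple(t) -> str:
    if t is None:
        return "-"
    point, lo, hi = t
    return (
        f"{fmt_pct(point)}"
        f"({_round_half_up(lo, 1):.1f} to {_round_half_up(hi, 1):.1f})"
    )


def _summary_triple(t):
    return None if t is None else {"point": t[0], "lower": t[1], "upper": t[2]}


def _cohort_for(cfg: RunConfig):
    if cfg.cohort_path is not None:
        return load_cohort(cfg.cohort_path, cfg.layout), "file"
    if cfg.generator is not None:
        return generate_cohort(cfg.generator), "generator"
    return reconstruct_fixture(packaged_counts_spec(), seed=cfg.seed), "fixture"


def _risk_entry(events, n, ci_level):
    r = crude_risk(events, n, ci_level)
    return {
        "events": events,
        "n": n,
        "risk_pct": r.risk_pct,
        "ci": list(r.ci),
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured analyses; returns the machine-readable summary
    (full precision) and, if ``out_dir`` is set, writes ``summary.json``
    and rendered tables.  Deterministic for a fixed config and seed."""
    cfg.validate()
    participants, source = _cohort_for(cfg)
    indexed = reduce_to_index(participants, size_key="volume")
    brock = brock_for_cohort(indexed)
    proto = cfg.protocol

    counts = marginal_counts(
        indexed,
        [(proto.rule_out_volume_mm3, "mm3"), (100.0, "mm3"),
         (proto.rule_out_diameter_mm, "mm"), (6.0, "mm")],
        FallbackRule(
            rule_out_diameter_mm=proto.fallback_rule_out_diameter_mm,
            rule_in_diameter_mm=proto.fallback_rule_in_diameter_mm,
            rule_in_volume_mm3=proto.rule_in_volume_mm3,
        ),
    )
    n_nod, n_canc = counts.n_nodule_participants, counts.n_nodule_cancers
    n_non, c_non = counts.n_no_nodule_participants, counts.n_no_nodule_cancers

    cfg_dict = asdict(cfg)
    cfg_dict.pop("out_dir")  # output location is not analysis configuration
    config_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    summary: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash,
        "cohort_source": source,
        "cohort": {
            "nodule_participants": n_nod,
            "nodule_cancers": n_canc,
            "no_nodule_participants": n_non,
            "no_nodule_cancers": c_non,
            "unsegmentable": counts.unsegmentable_count,
        },
    }

    fallback = FallbackRule(
        rule_out_diameter_mm=proto.fallback_rule_out_diameter_mm,
        rule_in_diameter_mm=proto.fallback_rule_in_diameter_mm,
        rule_in_volume_mm3=proto.rule_in_volume_mm3,
    )

    def ruleout_row(label, threshold, scale):
        b = next(
            x for x in counts.bins if x.scale == scale and x.threshold == threshold
        )
        rule = SizeRule(
            threshold,
            scale,
            fallback_diameter_mm=fallback.diameter_cut(threshold)
            if scale == "mm3"
            else None,
        )
        c = stratify(indexed, rule)
        d = diagnostic_summary(c, cfg.ci_level)
        chi2_stat, chi2_p = pearson_chi2(
            [
                [b.cancers_below, b.participants_below - b.cancers_below],
                [c_non, n_non - c_non],
            ]
        )
        return {
            "label": label,
            "risk": _risk_entry(b.cancers_below, b.participants_below, cfg.ci_level),
            "p_vs_no_nodules": chi2_p,
            "chi2_statistic": chi2_stat,
            "pct_within_threshold": 100.0 * b.participants_below / n_nod,
            "sensitivity": _summary_triple(d.sensitivity),
            "specificity": _summary_triple(d.specificity),
            "npv": _summary_triple(d.npv),
        }

    if "table1" in cfg.analyses:
        any_chi2, any_p = pearson_chi2(
            [[n_canc, n_nod - n_canc], [c_non, n_non - c_non]]
        )
        summary["table1"] = {
            "no_nodules": _risk_entry(c_non, n_non, cfg.ci_level),
            "any_solid_nodule": {
                **_risk_entry(n_canc, n_nod, cfg.ci_level),
                "p_vs_no_nodules": any_p,
            },
            "rows": [
                ruleout_row("<5 mm", proto.rule_out_diameter_mm, "mm"),
                ruleout_row("<6 mm", 6.0, "mm"),
                ruleout_row("<80 mm3", proto.rule_out_volume_mm3, "mm3"),
                ruleout_row("<100 mm3", 100.0, "mm3"),
            ],
        }

    rule_diam = SizeRule(proto.rule_in_diameter_mm, "mm")
    rule_vol = SizeRule(
        proto.rule_in_volume_mm3,
        "mm3",
        fallback_diameter_mm=proto.fallback_rule_in_diameter_mm,
    )

    if "table2" in cfg.analyses:
        def rulein_entry(rule, gated):
            r = BrockGatedRule(rule, proto.brock_threshold) if gated else rule
            c = stratify(indexed, r, brock=brock)
            d = diagnostic_summary(c, cfg.ci_level)
            return {
                "rule": r.describe(),
                "tp": c.tp,
                "meeting": c.positives,
                "sensitivity": _summary_triple(d.sensitivity),
                "specificity": _summary_triple(d.specificity),
                "ppv": _summary_triple(d.ppv),
            }, c

        diam_entry, c_diam = rulein_entry(rule_diam, False)
        vol_entry, c_vol = rulein_entry(rule_vol, False)
        diam_b_entry, c_diam_b = rulein_entry(rule_diam, True)
        vol_b_entry, c_vol_b = rulein_entry(rule_vol, True)

        # discordant pairs for sens (among cancers) and spec (among benign)
        pos_d = {
            p.participant_id: rule_diam.is_positive(p)
            for p in indexed
            if p.index_nodule is not None
        }
        pos_v = {
            p.participant_id: rule_vol.is_positive(p)
            for p in indexed
            if p.index_nodule is not None
        }
        canc = [p for p in indexed if p.index_nodule is not None and p.outcome]
        ben = [p for p in indexed if p.index_nodule is not None and not p.outcome]
        b_s = sum(
            pos_d[p.participant_id] and not pos_v[p.participant_id] for p in canc
        )
        c_s = sum(
            pos_v[p.participant_id] and not pos_d[p.participant_id] for p in canc
        )
        b_p = sum(
            not pos_d[p.participant_id] and pos_v[p.participant_id] for p in ben
        )
        c_p = sum(
            not pos_v[p.participant_id] and pos_d[p.participant_id] for p in ben
        )
        summary["table2"] = {
            "size_alone": {"diameter": diam_entry, "volume": vol_entry},
            "with_brock": {"diameter": diam_b_entry, "volume": vol_b_entry},
            "p_sens_diam_vs_vol": mcnemar(b_s, c_s) if b_s + c_s else None,
            "p_spec_diam_vs_vol": mcnemar(b_p, c_p) if b_p + c_p else None,
            "fp_reduction_volume_pct": false_positive_reduction(
                c_vol.fp, c_vol_b.fp
            )
            if c_vol.fp
            else None,
            "fp_reduction_diameter_pct": false_positive_reduction(
                c_diam.fp, c_diam_b.fp
            )
            if c_diam.fp
            else None,
        }

    if "net_benefit" in cfg.analyses:
        rule_out_ref = SizeRule(
            proto.rule_out_volume_mm3,
            "mm3",
            fallback_diameter_mm=proto.fallback_rule_out_diameter_mm,
        )
        rule_out_new = SizeRule(
            100.0,
            "mm3",
            fallback_diameter_mm=proto.fallback_rule_out_diameter_mm,
        )
        comparisons = {
            "rule_out_80_to_100": (
                rule_out_ref, rule_out_new, cfg.nb_weight_rule_out
            ),
            "rule_in_diameter_add_brock": (
                rule_diam,
                BrockGatedRule(rule_diam, proto.brock_threshold),
                cfg.nb_weight_rule_in,
            ),
            "rule_in_volume_add_brock": (
                rule_vol,
                BrockGatedRule(rule_vol, proto.brock_threshold),
                cfg.nb_weight_rule_in,
            ),
        }
        nb = {}
        for name, (ref, new, w) in comparisons.items():
            res = bootstrap_net_benefit(
                indexed,
                ref,
                new,
                weight_W=w,
                prevalence_source=cfg.nb_prevalence_source,
                B=cfg.n_bootstrap,
                seed=cfg.seed,
                brock=brock,
                ci_level=cfg.ci_level,
            )
            nb[name] = {
                "reference": ref.describe(),
                "new": new.describe(),
                "point": res.point_estimate,
                "ci": list(res.ci),
                "weight_W": w,
                "prevalence_source": res.prevalence_source,
                "prevalence_p": res.prevalence_p,
                "n_bootstrap": res.n_bootstrap,
                "n_redrawn": res.n_redrawn,
            }
        summary["net_benefit"] = nb

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        (out / "report.txt").write_text(render_table(summary), encoding="utf-8")
    return summary


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _risk_cell(e) -> str:
    return (
        f"{e['events']}/{e['n']}\t{fmt_pct(e['risk_pct'], 2)}"
        f"({e['ci'][0]:.2f} to {e['ci'][1]:.2f})"
    )


def render_table(summary: dict, style: str = "text") -> str:
    """Render the summary in the cohort tables' house style."""
    if style not in ("text", "delimited"):
        raise ConfigurationError(f"unknown style {style!r}")
    lines: list[str] = []
    t1 = summary.get("table1")
    if t1:
        lines.append("Rule-out threshold performance (per participant)")
        lines.append(
            "Threshold\tCancers/participants\tRisk(95% CI)\tP value\t"
            "% within threshold\tSensitivity(95% CI)\tSpecificity(95% CI)\t"
            "NPV(95% CI)"
        )
        lines.append(f"No nodules\t{_risk_cell(t1['no_nodules'])}\t-\t\t\t\t")
        a = t1["any_solid_nodule"]
        lines.append(
            f"Any solid nodule\t{a['events']}/{a['n']}\t"
            f"{fmt_pct(a['risk_pct'], 2)}({a['ci'][0]:.2f} to {a['ci'][1]:.2f})\t"
            f"{fmt_p(a['p_vs_no_nodules'])}\t100%\t-\t-\t-"
        )
        for row in t1["rows"]:
            lines.append(
                f"{row['label']}\t{_risk_cell(row['risk'])}\t"
                f"{fmt_p(row['p_vs_no_nodules'])}\t"
                f"{fmt_pct(row['pct_within_threshold'])}\t"
                f"{_fmt_triple(tuple(row['sensitivity'].values()))}\t"
                f"{_fmt_triple(tuple(row['specificity'].values()))}\t"
                f"{_fmt_triple(tuple(row['npv'].values()))}"
            )
        lines.append("")
    t2 = summary.get("table2")
    if t2:
        lines.append("Rule-in threshold performance, size alone and with Brock gate")
        for block_name, block in (
            ("size alone", t2["size_alone"]),
            ("with Brock", t2["with_brock"]),
        ):
            for scale in ("diameter", "volume"):
                e = block[scale]
                lines.append(
                    f"{e['rule']} ({block_name})\t{e['tp']}/{e['meeting']}\t"
                    f"sens {_fmt_triple(tuple(e['sensitivity'].values()))}\t"
                    f"spec {_fmt_triple(tuple(e['specificity'].values()))}\t"
                    f"PPV {_fmt_triple(tuple(e['ppv'].values()))}"
                )
        if t2.get("p_sens_diam_vs_vol") is not None:
            lines.append(
                "McNemar p (sens, diam vs vol): "
                f"{fmt_p(t2['p_sens_diam_vs_vol'])}; "
                f"(spec): {fmt_p(t2['p_spec_diam_vs_vol'])}"
            )
        lines.append("")
    nb = summary.get("net_benefit")
    if nb:
        lines.append("Weighted net-benefit comparisons")
        for name, e in nb.items():
            lines.append(
                f"{name}: {e['new']} vs {e['reference']} (W={e['weight_W']:g}, "
                f"p={e['prevalence_p']:.4f} [{e['prevalence_source']}]): "
                f"{e['point']:+.2f} (95% CI {e['ci'][0]:.2f} to {e['ci'][1]:.2f})"
            )
        lines.append("")
    if style == "text":
        return "\n".join(lines)
    return "\n".join(lines)
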