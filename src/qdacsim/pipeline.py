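"""End-to-end orchestration: simulate → label → (ligate) → qPCR → quantify.

A run is driven by a scenario YAML with ``population``, ``labeling``,
``capture``, ``qpcr``, ``pla`` and ``quantify`` blocks. One global seed is
expanded into independent per-stage streams through
``numpy.random.SeedSequence.spawn`` (fixed order: population, labeling,
capture, pla, standards, sample wells), so any stage can be rerun in
isolation. Every artifact embeds the config hash, the seed and the package
version; reruns with equal seed and config are byte-identical apart from
nothing (no timestamps are written).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__, oligos, pla, qpcr, quantify, stoichiometry, synthetic

__all__ = ["RunConfig", "load_scenario", "run_pipeline", "validate_fixtures", "scenario_path"]

logger = logging.getLogger(__name__)

MODES = ("direct", "pla")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline invocation."""

    scenario: str | Path
    seed: int
    replicates: int = 3
    output_dir: str | Path = "qdacsim_run"
    mode: str = "direct"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")


def scenario_path(name: str) -> Path:
    """Path of a packaged scenario file (e.g. ``'epcam_worked_example'``)."""
    from importlib import resources

    return Path(str(resources.files("qdacsim").joinpath(f"data/scenarios/{name}.yaml")))


def load_scenario(path: str | Path) -> dict:
    """Load and structurally validate a scenario YAML."""
    with open(path) as fh:
        scenario = yaml.safe_load(fh)
    if not isinstance(scenario, dict):
        raise ValueError(f"scenario file {path} must contain a mapping")
    unknown = set(scenario) - {
        "name", "population", "labeling", "capture", "qpcr", "pla", "quantify", "worked_example",
    }
    if unknown:
        raise ValueError(f"scenario {path}: unknown top-level block(s) {sorted(unknown)}")
    for block in ("population", "qpcr"):
        if block not in scenario:
            raise ValueError(f"scenario {path}: required block {block!r} missing")
    return scenario


def _config_hash(scenario: dict) -> str:
    return hashlib.sha256(json.dumps(scenario, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full in-silico assay and write its artifacts.

    Writes ``plate.csv`` (standard series + sample wells), ``curve.json``
    (the refit standard curve), ``result.json`` (estimates, ground truth,
    provenance) and ``report.md`` to ``config.output_dir``; returns the
    result dictionary. Failures are re-raised with the failing stage named;
    artifacts written before the failure are retained.
    """
    scenario = load_scenario(config.scenario)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(6)]
    rng_pop, rng_label, rng_capture, rng_pla, rng_std, rng_sample = streams

    stage = "population"
    try:
        pop_block = dict(scenario.get("population", {}))
        pop_block["seed"] = int(rng_pop.integers(2**31))
        pop = synthetic.simulate_population(synthetic.EVPopulationParams(**pop_block))

        stage = "labeling"
        lab = dict(scenario.get("labeling", {}))
        labeled = synthetic.label_population(
            pop,
            p_bind=float(lab.get("p_bind", 0.3)),
            dual_label=config.mode == "pla",
            nonspecific_rate=float(lab.get("nonspecific_rate", 0.0)),
            dna_per_conjugate=int(lab.get("dna_per_conjugate", 3)),
            seed=rng_label,
        )

        stage = "capture"
        cap = dict(scenario.get("capture", {}))
        sample = synthetic.capture_wash_elute(
            labeled,
            capture_eff=float(cap.get("capture_eff", 1.0)),
            wash_retention=float(cap.get("wash_retention", 1.0)),
            eluate_volume=float(cap.get("eluate_volume", 100.0)),
            seed=rng_capture,
        )

        stage = "pla"
        measured_conc = sample.dna_conc_true
        ligation = None
        if config.mode == "pla":
            pla_block = dict(scenario.get("pla", {}))
            outcome = pla.simulate_pla(
                sample.ev_records,
                pla.PLAConfig(
                    p_ligate=float(pla_block.get("p_ligate", 0.9)),
                    background_rate=float(pla_block.get("background_rate", 0.0)),
                ),
                seed=rng_pla,
            )
            measured_conc = synthetic.strands_to_nM(outcome.templates, sample.eluate_volume)
            ligation = {
                "templates": outcome.templates,
                "from_ev": outcome.from_ev,
                "from_background": outcome.from_background,
            }

        stage = "qpcr"
        q = dict(scenario["qpcr"])
        true_curve = qpcr.StandardCurve(slope=float(q["slope"]), intercept=float(q["intercept"]))
        noise_sd = float(q.get("noise_sd", qpcr.DEFAULT_NOISE_SD))
        max_cycles = float(q.get("max_cycles", qpcr.DEFAULT_MAX_CYCLES))
        ref_conc = float(q.get("ref_conc_nM", 10.0))
        std_xs = list(q.get("standard_xs", [0.0, 1.0, 2.0, 3.0, 4.0]))
        std_reps = int(q.get("standard_replicates", 3))
        wells = []
        for x in std_xs:
            for rep in range(std_reps):
                wells.append(
                    qpcr.simulate_ct(
                        float(x), true_curve, noise_sd=noise_sd, max_cycles=max_cycles,
                        seed=rng_std, well_id=f"STD_x{x}_r{rep}", target="standard",
                    )
                )
        fitted = qpcr.fit_standard_curve([w for w in wells if w.target == "standard"])
        fitted.to_json(out_dir / "curve.json")

        x_sample = math.inf if measured_conc <= 0 else -math.log10(measured_conc / ref_conc)
        for rep in range(config.replicates):
            wells.append(
                qpcr.simulate_ct(
                    x_sample, true_curve, noise_sd=noise_sd, max_cycles=max_cycles,
                    seed=rng_sample, well_id=f"SMP_r{rep}", target="sample",
                )
            )
        qpcr.write_plate(wells, out_dir / "plate.csv")

        stage = "quantify"
        qt = dict(scenario.get("quantify", {}))
        qcfg = quantify.QuantConfig(
            ref_conc_nM=ref_conc,
            dna_per_ab=float(qt.get("dna_per_ab", 3.0)),
            mw_kda=float(qt.get("mw_kda", quantify.DEFAULT_MW_KDA)),
            target="sample",
        )
        result = quantify.quantify_run(wells, fitted, qcfg)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    truth_mass = quantify.antibody_to_mass(
        quantify.dna_to_antibody(sample.dna_conc_true, qcfg.dna_per_ab), qcfg.mw_kda
    )
    payload = {
        "provenance": {
            "package": "qdacsim",
            "version": __version__,
            "seed": config.seed,
            "mode": config.mode,
            "config_hash": _config_hash(scenario),
            "scenario_name": scenario.get("name"),
        },
        "ground_truth": {
            "dna_conc_nM": sample.dna_conc_true,
            "measured_input_conc_nM": measured_conc,
            "antigen_mass_ng_ml": truth_mass,
            "n_ev_surviving": int(len(sample.ev_records)),
        },
        "ligation": ligation,
        "curve": {"slope": fitted.slope, "intercept": fitted.intercept, "r_squared": fitted.r_squared},
        "estimate": quantify.format_result(result),
        "estimate_full": {
            "dna_conc_nM": result.dna_conc,
            "ab_conc_nM": result.ab_conc,
            "antigen_mass_ng_ml": result.antigen_mass,
        },
    }
    if "worked_example" in scenario:
        we = scenario["worked_example"]
        dna, sd = float(we["dna_conc_nM"]), float(we["dna_sd_nM"])
        ratio = float(we.get("dna_per_ab", qcfg.dna_per_ab))
        mw = float(we.get("mw_kda", qcfg.mw_kda))
        ab = quantify.dna_to_antibody(dna, ratio)
        payload["worked_example"] = {
            "dna_conc_nM": dna,
            "dna_sd_nM": sd,
            "ab_conc_nM": round(ab, 2),
            "ab_sd_nM": round(quantify.propagate_sd(sd, [1 / ratio]), 2),
            "antigen_mass_ng_ml": float(f"{quantify.antibody_to_mass(ab, mw):.3g}"),
            "mass_sd_ng_ml": float(f"{quantify.propagate_sd(sd, [1 / ratio, mw]):.3g}"),
        }
    (out_dir / "result.json").write_text(json.dumps(payload, indent=2) + "\n")
    (out_dir / "report.md").write_text(_render_report(payload))
    return payload


def _render_report(payload: dict) -> str:
    est, truth = payload["estimate"], payload["ground_truth"]
    lines = [
        "# qdacsim run report",
        "",
        f"- scenario: {payload['provenance']['scenario_name']}  "
        f"(hash {payload['provenance']['config_hash']}, seed {payload['provenance']['seed']}, "
        f"mode {payload['provenance']['mode']}, qdacsim {payload['provenance']['version']})",
        "",
        "## Estimates vs ground truth",
        "",
        "| quantity | estimate | ground truth |",
        "|---|---|---|",
        f"| DNA concentration (nM) | {est['dna_conc_nM']} ± {est['dna_sd_nM']} | {truth['dna_conc_nM']:.4g} |",
        f"| antibody concentration (nM) | {est['ab_conc_nM']} ± {est['ab_sd_nM']} | — |",
        f"| antigen mass (ng/mL) | {est['antigen_mass_ng_ml']} ± {est['mass_sd_ng_ml']} | {truth['antigen_mass_ng_ml']:.4g} |",
        "",
        f"Standard curve refit: slope {payload['curve']['slope']:.4g}, "
        f"intercept {payload['curve']['intercept']:.4g}, R² {payload['curve']['r_squared']:.6g}.",
        f"Wells used: {est['n_wells_used']}, undetermined: {est['n_undetermined']}.",
    ]
    if payload.get("ligation"):
        lig = payload["ligation"]
        lines += [
            "",
            f"Proximity ligation: {lig['templates']} templates "
            f"({lig['from_ev']} vesicle-borne, {lig['from_background']} background).",
        ]
    if payload.get("worked_example"):
        we = payload["worked_example"]
        lines += [
            "",
            "## Reference conversion chain",
            "",
            f"Measured conjugate DNA {we['dna_conc_nM']} ± {we['dna_sd_nM']} nM "
            f"→ antibody {we['ab_conc_nM']} ± {we['ab_sd_nM']} nM (÷3) "
            f"→ antigen {we['antigen_mass_ng_ml']} ± {we['mass_sd_ng_ml']} ng/mL at MW 29.1 kDa.",
        ]
    return "\n".join(lines) + "\n"


def validate_fixtures() -> dict:
    """Run the packaged oligo-panel and analytic self-checks.

    Returns ``{"ok": bool, "checks": [...]}`` where each check carries a
    status of ``pass``, ``fail`` or ``warn``. Documented print
    discrepancies in the source designs (the EXO-R 3'-end mismatch, the
    connector's partial complementarity) are warnings, not failures.
    """
    checks: list[dict] = []

    def add(name: str, ok: bool, detail: str, warn: bool = False) -> None:
        # warn=True marks a documented known discrepancy: reported as a
        # warning while the discrepancy holds, a failure if it disappears.
        if warn:
            status = "warn" if ok else "fail"
        else:
            status = "pass" if ok else "fail"
        checks.append({"name": name, "status": status, "detail": detail})

    try:
        panel = oligos.load_table1()
    except Exception as exc:  # pragma: no cover - broken install
        return {"ok": False, "checks": [{"name": "fixture_load", "status": "fail", "detail": str(exc)}]}

    add("fixture_records", len(panel) == 13, f"{len(panel)} records loaded")
    nine = panel["EXOpcr-69-bio"]
    add("reporter_69mer_length", len(nine) == 69, f"length {len(nine)}")

    c1, c2, c1c2 = panel["Proximity_C1"], panel["Proximity_C2"], panel["C1C2"]
    try:
        product = oligos.ligate(c1, c2, connector=panel["Proximity_cnct"])
        add("c1c2_ligation", product.sequence == c1c2.sequence,
            f"ligated length {len(product)} vs printed {len(c1c2)}")
    except oligos.OligoError as exc:
        add("c1c2_ligation", False, str(exc))

    add("proximity_f_in_c1", panel["Proximity_F"].sequence in c1.sequence,
        "forward primer sits on C1")
    add("proximity_r_in_c2",
        oligos.reverse_complement(panel["Proximity_R"].sequence) in c2.sequence,
        "reverse-primer site sits on C2")
    add("probe_in_reporter",
        oligos.reverse_complement(panel["Probe-Rox"].sequence) in nine.sequence,
        "probe hybridizes to the 69-mer")
    add("exo_f_prefix", nine.sequence.startswith(panel["EXO-F"].sequence),
        "EXO-F is the 69-mer 5' end")

    try:
        hit = oligos.find_amplicon(c1c2, panel["Proximity_F"], panel["Proximity_R"])
        add("c1c2_amplicon", hit.length == 87, f"amplicon [{hit.start}, {hit.end}) = {hit.length} nt")
    except oligos.AmpliconNotFoundError as exc:
        add("c1c2_amplicon", False, str(exc))

    # Known print discrepancy: rc(EXO-R) mismatches the 69-mer 3' end.
    exo_r_site = oligos.reverse_complement(panel["EXO-R"].sequence)
    add("exo_r_site_known_mismatch", exo_r_site not in nine.sequence,
        "rc(EXO-R) absent from the 69-mer as printed (documented design typo)", warn=True)
    add("connector_partial_complementarity", True,
        "connector bridging geometry is metadata only; not sequence-verified", warn=True)

    p = stoichiometry.prob_multivalent_antibody(stoichiometry.WORKING_LAMBDA)
    add("multivalence_at_1_80", float(f"{p:.2g}") == 7.7e-5, f"P(n>1, 1/80) = {p:.6g}")
    mix_lam = stoichiometry.lambda_from_mix(stoichiometry.WORKING_MIX)
    add("working_mix_ratio_known_discrepancy", abs(mix_lam - 0.125) < 1e-12,
        f"pipetted mix computes to λ = {mix_lam:.4g}, quoted working ratio is 1/80", warn=True)

    ok = all(c["status"] != "fail" for c in checks)
    return {"ok": ok, "checks": checks}
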