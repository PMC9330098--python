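"""End-to-end orchestration of the consensus screening funnel.

Stages, in order (mirroring the screening workflow): generate or load a
labeled world -> standardize/deduplicate -> robust PLIFs -> mine the
residue signature -> assemble feature blocks -> train/test the QSAR
ensemble -> fit the RDN applicability domain -> screen the library
through the docking rules and the QSAR model -> consensus selection ->
novelty report.  Per-stage input/output counts (the funnel) and the
config hash go into a JSON run manifest; re-running with an identical
config reproduces every artifact.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from plifscreen._version import __version__
from plifscreen.config import RunConfig
from plifscreen.curation import (
    ACTIVE,
    compute_feature_matrix,
    prefilter_library,
    standardize_and_dedupe,
)
from plifscreen.plif import (
    DEFAULT_KEY_RESIDUES,
    InteractionFingerprint,
    load_reference_fingerprint,
    plif_matrix,
    plif_tanimoto,
    similarity_percentile_cutoff,
)
from plifscreen.qsar import (
    EnsembleForestClassifier,
    RDNReliability,
    cross_validated_correctness,
    evaluate,
    optimize_hyperparameters,
    predict_majority,
    split_train_test,
)
from plifscreen.screen import (
    consensus_select,
    docking_rules_filter,
    mcs_anchor_sizes,
    novelty_report,
)
from plifscreen.signatures import SignatureMiner
from plifscreen.simulate import simulate_labeled_set, simulate_library

logger = logging.getLogger("plifscreen")


def _setup_logging(out_dir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    stream.setFormatter(logging.Formatter("[%(name)s] %(message)s"))
    logger.addHandler(stream)
    fileh = logging.FileHandler(out_dir / "run.log", mode="w")
    fileh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(fileh)


def _similarities(fp_frame: pd.DataFrame, reference: InteractionFingerprint,
                  subset) -> np.ndarray:
    vocab = tuple(fp_frame.columns)
    sims = np.empty(len(fp_frame))
    ref = reference
    if ref.vocabulary != vocab:
        # align the reference onto the working vocabulary
        ref_on = ref.on_residues() & set(vocab)
        ref = InteractionFingerprint.from_residues(ref_on, vocab)
    for i, (_, row) in enumerate(fp_frame.iterrows()):
        fp = InteractionFingerprint(vocabulary=vocab, bits=row.to_numpy())
        sims[i] = plif_tanimoto(fp, ref, subset=subset)
    return sims


def _feature_blocks(smiles, plif_frame: pd.DataFrame, key_residues) -> dict:
    physchem, morgan = compute_feature_matrix(list(smiles))
    residue = plif_frame[list(key_residues)].to_numpy(dtype=float)
    return {
        "physchem": physchem.to_numpy(dtype=float),
        "morgan": morgan.astype(float),
        "residue_contacts": residue,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full funnel; returns the run manifest (also written to disk).

    Artifacts (curated table, PLIF matrices, rules table, predictions,
    hits and novelty tables) are written under ``config.output_dir``
    together with ``manifest.json``.  Stage failures abort with the
    stage name after writing a partial manifest.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir)
    config.save(out_dir / "config.yaml")

    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "funnel": {},
        "stages": [],
    }
    funnel = manifest["funnel"]

    def stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    def fail(name: str, exc: Exception):
        manifest["failed_stage"] = name
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    sim_cfg = config.simulate.with_seed(config.seed)
    key_residues = [r for r in DEFAULT_KEY_RESIDUES if r in sim_cfg.residue_vocabulary]

    try:
        stage("simulate_labeled_set")
        records, tables, labels = simulate_labeled_set(sim_cfg)
        funnel["labeled_compounds"] = len(records)

        stage("standardize_and_dedupe")
        curated, rejects = standardize_and_dedupe(records.assign(value_um=np.nan))
        curated["label"] = records["label"].to_numpy()  # labels come from the generator
        curated.to_csv(out_dir / "curated.csv", index=False)
        funnel["curated_compounds"] = len(curated)
        funnel["rejected_structures"] = len(rejects)

        stage("robust_plifs")
        fp_frame = plif_matrix(
            tables,
            top_n=config.plif.top_n,
            min_poses=config.plif.min_poses,
            vocabulary=sim_cfg.residue_vocabulary,
        )
        fp_frame.to_csv(out_dir / "plifs_train.csv")

        stage("mine_signature")
        miner = SignatureMiner(
            min_size=config.mining.min_size,
            max_size=config.mining.max_size,
            min_coverage=config.mining.min_coverage,
            residues=key_residues,
        )
        miner.fit(fp_frame, labels)
        miner.rules_table().to_csv(out_dir / "signature_rules.csv", index=False)
        rule = miner.rule_
        funnel["signatures_scored"] = len(miner.rules_)
        manifest["selected_signature"] = list(rule.sorted_residues())
        manifest["signature_ratio"] = rule.ratio if np.isfinite(rule.ratio) else "inf"
        manifest["signature_coverage"] = rule.coverage
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        fail(manifest["stages"][-1], exc)

    try:
        stage("train_qsar")
        blocks = _feature_blocks(records["smiles"], fp_frame, key_residues)
        n = len(records)
        train_df, test_df = split_train_test(
            pd.DataFrame({"row": np.arange(n), "label": labels}),
            test_fraction=config.qsar.test_fraction,
            seed=config.seed,
        )
        tr, te = train_df["row"].to_numpy(), test_df["row"].to_numpy()
        funnel["train_rows"], funnel["test_rows"] = len(tr), len(te)

        if config.qsar.optimize:
            opt = optimize_hyperparameters(
                {k: v[tr] for k, v in blocks.items()},
                labels[tr],
                trees_grid=config.qsar.trees_grid,
                cv_folds=config.qsar.cv_folds,
                seed=config.seed,
            )
            n_trees, use_blocks = opt.n_trees, list(opt.blocks)
            manifest["optimizer"] = {
                "n_trees": n_trees, "blocks": use_blocks,
                "cv_mean": opt.cv_mean, "cv_sd": opt.cv_sd,
            }
        else:
            n_trees, use_blocks = config.qsar.n_trees, list(config.qsar.blocks)

        X = np.hstack([blocks[b] for b in use_blocks])
        model = EnsembleForestClassifier(
            n_members=config.qsar.n_members,
            n_trees=n_trees,
            bag_fraction=config.qsar.bag_fraction,
            random_state=config.seed,
        )
        model.fit(X[tr], labels[tr])
        test_pred = predict_majority(model, X[te], compound_ids=records["compound_id"].iloc[te])
        metrics = evaluate(test_pred["predicted_label"], labels[te])
        manifest["qsar_test"] = {
            "accuracy": metrics.accuracy,
            "precision_active": metrics.precision_active,
            "precision_inactive": metrics.precision_inactive,
        }

        stage("fit_applicability_domain")
        correct = cross_validated_correctness(
            blocks["morgan"][tr], labels[tr],
            cv_folds=min(config.qsar.cv_folds, 5), seed=config.seed,
        )
        rdn = RDNReliability(bandwidth=config.qsar.rdn_bandwidth)
        rdn.fit(blocks["morgan"][tr], correct)
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(manifest["stages"][-1], exc)

    try:
        stage("simulate_library")
        lib_records, lib_tables, truth = simulate_library(sim_cfg)
        truth.to_csv(out_dir / "library_truth.csv", index=False)
        funnel["library_compounds"] = len(lib_records)

        if config.curation.apply_prefilter:
            stage("prefilter_library")
            lib_keep, counts = prefilter_library(
                lib_records, qed_min=config.curation.qed_min, pains=config.curation.pains
            )
            keep_ids = set(lib_keep["compound_id"])
            lib_tables = [t for t in lib_tables if t.compound_id in keep_ids]
            lib_records = lib_keep.reset_index(drop=True)
            funnel["library_after_prefilter"] = len(lib_records)

        stage("library_plifs")
        lib_fps = plif_matrix(
            lib_tables,
            top_n=config.plif.top_n,
            min_poses=config.plif.min_poses,
            vocabulary=sim_cfg.residue_vocabulary,
        )

        stage("docking_rules")
        reference = load_reference_fingerprint(config.plif.reference_fingerprint)
        sims = _similarities(lib_fps, reference, subset=key_residues)
        if config.plif.sim_cutoff is not None:
            cutoff = config.plif.sim_cutoff
        else:
            cutoff = similarity_percentile_cutoff(sims, config.plif.similarity_percentile)
        manifest["similarity_cutoff"] = cutoff
        rules_out = docking_rules_filter(
            lib_fps, rule, sims, sim_cutoff=cutoff,
            compound_ids=lib_records["compound_id"],
        )
        funnel["docking_candidates"] = int(rules_out["docking_candidate"].sum())

        stage("qsar_screen")
        lib_blocks = _feature_blocks(lib_records["smiles"], lib_fps, key_residues)
        X_lib = np.hstack([lib_blocks[b] for b in use_blocks])
        lib_pred = predict_majority(model, X_lib, compound_ids=lib_records["compound_id"])
        lib_pred["reliability"] = rdn.score_samples(lib_blocks["morgan"])
        # accept the most reliable fraction of library predictions
        rel_cut = float(np.quantile(lib_pred["reliability"], 1 - config.qsar.ad_coverage))
        lib_pred["accepted"] = lib_pred["reliability"] >= rel_cut
        lib_pred.to_csv(out_dir / "library_predictions.csv", index=False)
        qsar_active = (lib_pred["predicted_label"] == ACTIVE) & lib_pred["accepted"]
        funnel["qsar_accepted_actives"] = int(qsar_active.sum())

        stage("consensus")
        results = rules_out.copy()
        results["qsar_accepted_active"] = qsar_active.to_numpy()
        # MCS anchor only for docking candidates (the docking AD filter)
        train_actives = records.loc[labels == ACTIVE, "smiles"]
        refs = list(train_actives.iloc[: config.screen.n_mcs_refs])
        results["mcs_anchor_size"] = 0
        cand_mask = results["docking_candidate"].to_numpy()
        if cand_mask.any():
            cand_smiles = lib_records.loc[cand_mask, "smiles"]
            mcs = mcs_anchor_sizes(
                cand_smiles, refs,
                min_mcs_atoms=config.screen.min_mcs_atoms,
                timeout=config.screen.mcs_timeout,
            )
            results.loc[cand_mask, "mcs_anchor_size"] = mcs["mcs_anchor_size"].to_numpy()
        hits = consensus_select(results, k=config.screen.k)
        hits = hits.merge(lib_records, on="compound_id", how="left")
        hits.to_csv(out_dir / "hits.csv", index=False)
        funnel["consensus_tier1"] = int((hits["consensus_tier"] == "qsar∩docking").sum())
        funnel["selected_hits"] = len(hits)

        stage("novelty")
        if len(hits):
            novelty = novelty_report(
                hits["smiles"], records["smiles"],
                min_mcs_atoms=config.screen.min_mcs_atoms,
                timeout=config.screen.mcs_timeout,
                hit_ids=list(hits["compound_id"]),
                train_ids=list(records["compound_id"]),
            )
        else:
            novelty = pd.DataFrame()
        novelty.to_csv(out_dir / "novelty.csv", index=False)
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001
        fail(manifest["stages"][-1], exc)

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("funnel: %s", funnel)
    return manifest
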