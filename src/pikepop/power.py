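"""Threshold classification of assignment output and power evaluation
against simulation truth, plus the end-to-end pipeline."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeError
from .hybrids import HYBRID_LABELS, PARENTAL_LABELS

UNASSIGNED = "UNASSIGNED"

THRESHOLDS = (0.5, 0.75, 0.9)


def classify(q: pd.DataFrame, threshold: float = 0.5) -> pd.Series:
    """Assign each individual to its modal class iff that class' membership
    strictly exceeds *threshold*, else ``UNASSIGNED``."""
    if threshold <= 1.0 / q.shape[1]:
        warnings.warn(
            f"threshold {threshold} <= 1/{q.shape[1]}: every row is assignable",
            stacklevel=2,
        )
    arr = q.to_numpy()
    best = arr.argmax(axis=1)
    ok = arr[np.arange(len(arr)), best] > threshold
    out = np.where(ok, q.columns.to_numpy()[best], UNASSIGNED)
    return pd.Series(out, index=q.index, name="class")


@dataclass
class PowerReport:
    """Error rates of hybrid detection at one threshold.

    Detection counts a true hybrid assigned to *any* hybrid class as a
    success, regardless of the exact class; false negatives are true
    hybrids assigned to a parental class.  For true hybrids,
    detection + false_negative + unassigned = 1.
    """

    threshold: float
    n_parental: int
    n_hybrid: int
    assigned_fraction: float
    false_positive_rate: float
    false_negative_rate: float
    detection_rate: float
    unassigned_hybrid_rate: float
    confusion: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "confusion"}
        d["confusion"] = self.confusion.to_dict()
        return d


def eval_rates(
    classified: pd.Series | Sequence[str],
    truth: Sequence[str],
    parental: Sequence[str] = PARENTAL_LABELS,
    hybrid: Sequence[str] = HYBRID_LABELS,
    threshold: float = float("nan"),
) -> PowerReport:
    """Confusion-matrix power report for mixture individuals with known truth."""
    pred = list(classified)
    truth = list(truth)
    if len(pred) != len(truth):
        raise GenotypeError("classified/truth length mismatch")
    parental = set(parental)
    hybrid = set(hybrid)
    t = np.asarray(truth)
    p = np.asarray(pred)
    is_true_hyb = np.isin(t, list(hybrid))
    is_true_par = np.isin(t, list(parental))
    n_h, n_p = int(is_true_hyb.sum()), int(is_true_par.sum())
    fp = (
        float(np.mean(np.isin(p[is_true_par], list(hybrid)))) if n_p else 0.0
    )
    fn = (
        float(np.mean(np.isin(p[is_true_hyb], list(parental)))) if n_h else 0.0
    )
    det = (
        float(np.mean(np.isin(p[is_true_hyb], list(hybrid)))) if n_h else 0.0
    )
    unass_h = (
        float(np.mean(p[is_true_hyb] == UNASSIGNED)) if n_h else 0.0
    )
    classes = sorted(set(truth) | set(pred) | {UNASSIGNED})
    confusion = pd.crosstab(
        pd.Categorical(t, categories=classes),
        pd.Categorical(p, categories=classes),
        dropna=False,
    )
    confusion.index.name = "truth"
    confusion.columns.name = "assigned"
    return PowerReport(
        threshold=threshold,
        n_parental=n_p,
        n_hybrid=n_h,
        assigned_fraction=float(np.mean(p != UNASSIGNED)),
        false_positive_rate=fp,
        false_negative_rate=fn,
        detection_rate=det,
        unassigned_hybrid_rate=unass_h,
        confusion=confusion,
    )


def power_table(
    q: pd.DataFrame,
    truth: Sequence[str],
    thresholds: Sequence[float] = THRESHOLDS,
    parental: Sequence[str] = PARENTAL_LABELS,
    hybrid: Sequence[str] = HYBRID_LABELS,
) -> pd.DataFrame:
    """Rates across thresholds for one assignment matrix (mixture rows only)."""
    rows = []
    for th in thresholds:
        r = eval_rates(classify(q, th), truth, parental, hybrid, threshold=th)
        rows.append(
            {
                "threshold": th,
                "assigned": r.assigned_fraction,
                "false_positive": r.false_positive_rate,
                "false_negative": r.false_negative_rate,
                "detection": r.detection_rate,
                "unassigned_hybrids": r.unassigned_hybrid_rate,
            }
        )
    return pd.DataFrame(rows)


def replicate_agreement(qs: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Pairwise modal-class agreement between replicate assignment runs."""
    modes = [q.idxmax(axis=1) for q in qs]
    n = len(modes)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = float(np.mean(modes[i] == modes[j]))
    return pd.DataFrame(out, index=range(1, n + 1), columns=range(1, n + 1))


# ----------------------------------------------------------------------
# end-to-end pipeline
# ----------------------------------------------------------------------


def run_pipeline(config: Mapping, outdir: str | Path) -> dict:
    """Run validate -> correct -> filter -> stats/Ne -> simulate -> assign ->
    evaluate, writing TSV/JSON artefacts; deterministic given seeds.

    Config keys (all optional except an input source): ``genepop`` (path) or
    ``synthetic`` (truthy -> generated study), ``seed``, ``ref1``, ``ref2``,
    ``mcmc_iters``, ``mcmc_burn``, ``mc_reps``, ``boot``, ``mixture``.
    Returns a bundle dict; a stage failure marks the bundle partial and
    records the stage error instead of raising.
    """
    from . import datasets, diversity, hybrids, markers, ne
    from .assign import NewHybridsModel, SnapclustModel
    from .genepop import read_genepop

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    rng = np.random.default_rng(seed)
    bundle: dict = {"seed": seed, "stages": {}, "partial": False}

    def stage(name, fn):
        try:
            bundle["stages"][name] = "ok"
            return fn()
        except Exception as exc:  # noqa: BLE001 - reported, not hidden
            bundle["stages"][name] = f"error: {exc}"
            bundle["partial"] = True
            return None

    if config.get("genepop"):
        table = read_genepop(config["genepop"], config.get("dialect", "3-digit"))
        ref1 = config.get("ref1")
        ref2 = config.get("ref2")
    else:
        study = datasets.synthetic_study(seed=int(rng.integers(0, 2**31 - 1)))
        table = study.raw
        ref1 = config.get("ref1", "TRA")
        ref2 = config.get("ref2", "DRA")

    mc_reps = int(config.get("mc_reps", 500))
    boot = int(config.get("boot", 1000))

    def _validate():
        hw = markers.hw_battery(
            table, demem=mc_reps, batches=10, iters=mc_reps,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        hw.to_tsv(outdir / "hw_battery.tsv")
        k = int((hw.frame["p"] < hw.alpha).sum()) if len(hw.frame) else 0
        p_exc, crit = markers.binomial_excess(k, max(hw.n_defined, 1))
        model = markers.estimate_dropout(table)
        corrected = markers.correct_genotypes(
            table, model, seed=int(rng.integers(0, 2**31 - 1))
        )
        return hw, (k, p_exc, crit), model, corrected

    v = stage("validate", _validate)
    corrected = v[3] if v else table

    def _filter():
        from .genotypes import filter_loci

        # judge removal on the raw panel (imputation would mask the
        # missing-data pattern), then drop those loci from the corrected one
        _, report = filter_loci(table)
        removed = set(report.removed_names)
        keep = [j for j, l in enumerate(table.loci) if l.name not in removed]
        clean = corrected.subset(loci=keep)
        pd.DataFrame(report.removed, columns=["locus", "reason"]).to_csv(
            outdir / "filtered_loci.tsv", sep="\t", index=False
        )
        return clean, report

    f = stage("filter", _filter)
    clean = f[0] if f else corrected

    def _stats():
        s = diversity.summary_stats(table=clean, boot=boot,
                                    seed=int(rng.integers(0, 2**31 - 1)))
        s.to_tsv(outdir / "summary_stats.tsv")
        th = diversity.wc_theta(clean, boot=boot,
                                seed=int(rng.integers(0, 2**31 - 1)))
        d = diversity.jost_d(clean, boot=boot,
                             seed=int(rng.integers(0, 2**31 - 1)))
        pair = diversity.pairwise_matrix(clean, boot=min(boot, 1000),
                                         seed=int(rng.integers(0, 2**31 - 1)))
        pair.to_csv(outdir / "pairwise_theta.tsv", sep="\t")
        nes = {}
        for pop in clean.populations:
            try:
                nes[pop] = ne.estimate_ne(clean, pop,
                                          seed=int(rng.integers(0, 2**31 - 1)))
            except GenotypeError:
                nes[pop] = None
        pd.DataFrame(
            {
                p: {
                    "Ne": r.ne if r else np.nan,
                    "lo": r.ci_low if r else np.nan,
                    "hi": r.ci_high if r else np.nan,
                }
                for p, r in nes.items()
            }
        ).T.to_csv(outdir / "ne_ld.tsv", sep="\t")
        return s, th, d, nes

    st = stage("stats", _stats)

    def _power():
        scenario = hybrids.build_s1(
            clean, ref1, ref2, mixture=int(config.get("mixture", 50)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        iters = int(config.get("mcmc_iters", 50_000))
        burn = int(config.get("mcmc_burn", iters // 5))
        nh = NewHybridsModel(scenario.table, ref1=ref1, ref2=ref2).fit(
            iters=iters, burn=burn, seed=int(rng.integers(0, 2**31 - 1))
        )
        sc = SnapclustModel(scenario.table, ref1=ref1, ref2=ref2).fit(
            seed=int(rng.integers(0, 2**31 - 1))
        )
        mix_ids = scenario.mixture_ids
        reports = {}
        for name, res in (("mcmc", nh), ("em", sc)):
            res.q.to_csv(outdir / f"q_{name}.tsv", sep="\t")
            reports[name] = power_table(res.q.loc[mix_ids], scenario.truth)
            reports[name].to_csv(outdir / f"power_{name}.tsv", sep="\t",
                                 index=False)
        return scenario, reports

    pw = stage("power", _power)

    bundle["outdir"] = str(outdir)
    if st:
        bundle["global_theta"] = st[1].estimate
    if pw:
        bundle["power"] = {k: v.to_dict("records") for k, v in pw[1].items()}
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=str)
    return bundle
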