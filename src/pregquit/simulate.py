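"""Synthetic two-arm cessation-trial generator.

Generates cohorts with the statistical structure the downstream analysis
assumes — per-arm quit propensities, arm-asymmetric crossover to the
non-allocated product among participants failing on their allocated product,
incomplete end-of-pregnancy ascertainment, partial saliva-sample return among
self-reported quitters, log-normal assay panels, and a birth-outcome model —
so that every analysis stage is testable without participant-level trial data.

The default :class:`SimulationConfig` is calibrated to the motivating trial's
marginal rates: arm sizes 571/569 (e-cigarette / patch), ~55% saliva return
among self-reported quitters, non-allocated regular product use near 3% vs
18% by arm, baseline salivary cotinine with median ~115 ng/ml, birthweight
around 3.1 kg, and ~1% twin pregnancies.

Crossover is modelled only among allocated-product failures: a participant
who fails on her allocated product may switch to the other product and then
succeed at that product's own quit rate.  This mirrors the arithmetic of the
contamination worked example (see :mod:`pregquit.estimands`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .records import (Arm, AssayPanel, DeliveryRecord, Education, EopReport,
                      InfantOutcome, ParticipantBaseline, ParticipantRecord,
                      ProductUsePattern, WeeklyStatus)

ArmPair = Tuple[float, float]


def _pair(v: Union[float, Sequence[float]]) -> Tuple[float, float]:
    """Broadcast a scalar to a per-arm (ECIG, NRT) pair."""
    if isinstance(v, (int, float)):
        return (float(v), float(v))
    a, b = v
    return (float(a), float(b))


@dataclass
class SimulationConfig:
    """All generator parameters; defaults are the trial-like preset.

    Per-arm pairs are ordered (e-cigarette arm, patch arm).  Scalars are
    accepted for any per-arm field and broadcast to both arms.
    """

    n_per_arm: Tuple[int, int] = (571, 569)
    # probability of prolonged abstinence on the allocated product
    true_quit_prob: ArmPair = (0.118, 0.061)
    # among allocated-product failures: probability of using the other product
    crossover_prob: ArmPair = (0.032, 0.193)
    # success probability for a failure of this arm who switches products
    # (defaults mirror the other arm's product efficacy)
    rescue_quit_prob: ArmPair = (0.061, 0.118)
    followup_ascertainment_prob: ArmPair = (0.93, 0.91)
    saliva_return_prob: float = 0.551          # among self-reported quitters
    co_reading_prob: float = 0.10              # independent CO reading
    misreport_prob: float = 0.08               # self-reported quitter actually smoking
    relapse_after_delivery_prob: float = 0.05  # quitter reached late, relapsed since
    pp_only_prob: ArmPair = (0.103, 0.068)     # point-prevalence-only abstinence at EOP
    wk4_only_prob: ArmPair = (0.035, 0.02)     # week-4 point abstinence among smokers
    weekly_report_prob: float = 0.97
    reduce50_prob: ArmPair = (0.40, 0.32)      # >=50% reduction among EOP smokers
    reducer_saliva_prob: float = 0.30

    # baseline covariates
    age_median: float = 27.0
    age_log_sd: float = 0.22
    cigs_median: float = 10.0
    cigs_log_sd: float = 0.45
    ftcd_mean: float = 4.15
    ftcd_sd: float = 2.1
    baseline_cotinine_missing_prob: float = 0.07
    lives_with_smoker_prob: float = 0.588
    education_probs: Tuple[float, float, float] = (0.406, 0.492, 0.102)
    employed_prob: float = 0.466

    # assay panels as (median, log-scale sd) of log-normals
    cotinine_smoker: Tuple[float, float] = (115.0, 0.607)
    cotinine_abstinent: Tuple[float, float] = (2.0, 0.5)
    anabasine_smoker: Tuple[float, float] = (2.0, 0.5)
    anabasine_abstinent: Tuple[float, float] = (0.2, 0.5)
    co_smoker: Tuple[float, float] = (12.0, 0.4)
    co_abstinent: Tuple[float, float] = (3.0, 0.4)

    # allocated-product adherence (marginal targets per arm)
    start_prob: ArmPair = (0.846, 0.677)
    alloc_current_4wk_prob: ArmPair = (0.399, 0.225)
    alloc_current_eop_prob: ArmPair = (0.338, 0.056)
    alloc_regular_prob: ArmPair = (0.767, 0.513)
    alloc_5plus_first4_prob: ArmPair = (0.60, 0.35)

    # detail of the non-allocated use pattern, conditional on crossover
    nonalloc_eop_given_crossover: float = 0.45
    nonalloc_5plus_given_crossover: float = 0.5
    nonalloc_occ_given_crossover: float = 0.3

    tqd_set_prob: ArmPair = (0.732, 0.692)
    contacted_prob: float = 0.97
    withdrew_prob: float = 0.005

    # birth model
    twin_prob: float = 0.011
    preterm_prob_smoker: float = 0.115
    preterm_prob_abstinent: float = 0.075
    ga_term_mean: float = 39.3
    ga_term_sd: float = 1.2
    ga_preterm_mean: float = 34.0
    ga_preterm_sd: float = 2.0
    bw_mean_smoker: float = 3100.0
    bw_mean_abstinent: float = 3300.0
    bw_sd: float = 420.0
    bw_ga_slope: float = 140.0     # g per gestational week relative to week 39
    twin_bw_deficit: float = 350.0
    bw_missing_prob: float = 0.01
    ga_missing_prob: float = 0.005
    miscarriage_prob: float = 0.0045
    stillbirth_prob: float = 0.002
    neonatal_death_prob: float = 0.0045
    post_neonatal_death_prob: float = 0.0027
    nicu_prob: float = 0.088
    congenital_prob: float = 0.037
    cesarean_prob: float = 0.255

    seed: int = 2018

    _PROB_PAIRS = ("true_quit_prob", "crossover_prob", "rescue_quit_prob",
                   "followup_ascertainment_prob", "pp_only_prob", "wk4_only_prob",
                   "reduce50_prob", "start_prob", "alloc_current_4wk_prob",
                   "alloc_current_eop_prob", "alloc_regular_prob",
                   "alloc_5plus_first4_prob", "tqd_set_prob")
    _PROB_SCALARS = ("saliva_return_prob", "co_reading_prob", "misreport_prob",
                     "relapse_after_delivery_prob", "weekly_report_prob",
                     "reducer_saliva_prob", "baseline_cotinine_missing_prob",
                     "lives_with_smoker_prob", "employed_prob",
                     "nonalloc_eop_given_crossover", "nonalloc_5plus_given_crossover",
                     "nonalloc_occ_given_crossover", "contacted_prob", "withdrew_prob",
                     "twin_prob", "preterm_prob_smoker", "preterm_prob_abstinent",
                     "bw_missing_prob", "ga_missing_prob", "miscarriage_prob",
                     "stillbirth_prob", "neonatal_death_prob",
                     "post_neonatal_death_prob", "nicu_prob", "congenital_prob",
                     "cesarean_prob")

    def __post_init__(self) -> None:
        for name in self._PROB_PAIRS:
            setattr(self, name, _pair(getattr(self, name)))

    def validate(self) -> None:
        if len(self.n_per_arm) != 2 or min(self.n_per_arm) < 1:
            raise ValueError("n_per_arm must be two counts >= 1")
        for name in self._PROB_PAIRS:
            for p in getattr(self, name):
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name} contains invalid probability {p}")
        for name in self._PROB_SCALARS:
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} is an invalid probability: {p}")
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ValueError("education_probs must sum to 1")
        for name in ("ftcd_sd", "ga_term_sd", "ga_preterm_sd", "bw_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def trial_like_config(seed: int = 2018) -> SimulationConfig:
    """The preset whose large-sample cohorts match the motivating trial's margins."""
    return SimulationConfig(seed=seed)


def expected_itt_self_prolonged(config: SimulationConfig) -> Tuple[float, float]:
    """Analytic per-arm probability of an observed ITT self-reported prolonged
    abstinence call under the generator's independence assumptions.

    A participant contributes an event iff she quits (on the allocated product,
    or after switching) and her end-of-pregnancy status is ascertained; those
    lost to follow-up count as non-abstinent.
    """
    out = []
    for i in range(2):
        q = config.true_quit_prob[i]
        c = config.crossover_prob[i]
        r = config.rescue_quit_prob[i]
        asc = config.followup_ascertainment_prob[i]
        out.append((q + (1.0 - q) * c * r) * asc)
    return tuple(out)  # type: ignore[return-value]


def _lognormal(rng: np.random.Generator, median: float, log_sd: float,
               size: int) -> np.ndarray:
    return rng.lognormal(mean=math.log(median), sigma=log_sd, size=size)


def _simulate_arm(arm: Arm, arm_idx: int, n: int, cfg: SimulationConfig,
                  rng: np.random.Generator) -> List[ParticipantRecord]:
    # --- baseline covariates -------------------------------------------------
    age = _lognormal(rng, cfg.age_median, cfg.age_log_sd, n).clip(18.0, 45.0)
    gestation = rng.uniform(12.0, 24.0, n)
    cigs = np.maximum(1, np.rint(_lognormal(rng, cfg.cigs_median,
                                            cfg.cigs_log_sd, n))).astype(int)
    ftcd = np.clip(np.rint(rng.normal(cfg.ftcd_mean, cfg.ftcd_sd, n)),
                   0, 10).astype(int)
    base_cot = _lognormal(rng, *cfg.cotinine_smoker, n)
    base_cot_missing = rng.random(n) < cfg.baseline_cotinine_missing_prob
    lives = rng.random(n) < cfg.lives_with_smoker_prob
    edu_idx = rng.choice(3, size=n, p=cfg.education_probs)
    employed = rng.random(n) < cfg.employed_prob

    # --- quitting, crossover, ascertainment ---------------------------------
    quit_alloc = rng.random(n) < cfg.true_quit_prob[arm_idx]
    crossover = (~quit_alloc) & (rng.random(n) < cfg.crossover_prob[arm_idx])
    rescued = crossover & (rng.random(n) < cfg.rescue_quit_prob[arm_idx])
    quit = quit_alloc | rescued
    pp_only = (~quit) & (rng.random(n) < cfg.pp_only_prob[arm_idx])
    ascertained = rng.random(n) < cfg.followup_ascertainment_prob[arm_idx]
    relapsed = quit & (rng.random(n) < cfg.relapse_after_delivery_prob)
    misreport = rng.random(n) < cfg.misreport_prob

    self_abstinent = quit | pp_only        # would self-report EOP abstinence
    # currently smoking at validation time
    smoking_now = (~self_abstinent) | relapsed | (self_abstinent & misreport)

    # --- weekly timeline, lapses, EOP report ---------------------------------
    wk1_smoking_q = rng.random(n) < 0.3
    wk4_abst_pp = rng.random(n) < 0.4
    wk4_abst_sm = rng.random(n) < cfg.wk4_only_prob[arm_idx]
    weekly_missing = rng.random((n, 4)) >= cfg.weekly_report_prob
    lapses_q = np.minimum(rng.poisson(0.8, n), 5)
    lapses_pp = 6 + rng.poisson(2.0, n)
    lapses_sm = rng.poisson(2.0, n)

    reduce50 = rng.random(n) < cfg.reduce50_prob[arm_idx]
    red_ratio = rng.uniform(0.1, 0.5, n)
    nonred_ratio = rng.uniform(0.55, 1.2, n)

    # --- product use ----------------------------------------------------------
    started = rng.random(n) < cfg.start_prob[arm_idx]
    p_start = max(cfg.start_prob[arm_idx], 1e-9)
    alloc_eop = started & (rng.random(n)
                           < min(1.0, cfg.alloc_current_eop_prob[arm_idx] / p_start))
    p_reg_extra = max(0.0, (cfg.alloc_regular_prob[arm_idx]
                            - cfg.alloc_current_eop_prob[arm_idx]) / p_start)
    alloc_regular = alloc_eop | (started & (rng.random(n) < min(1.0, p_reg_extra)))
    alloc_4wk = alloc_regular & (
        rng.random(n) < min(1.0, cfg.alloc_current_4wk_prob[arm_idx]
                            / max(cfg.alloc_regular_prob[arm_idx], 1e-9)))
    alloc_5plus = started & (
        rng.random(n) < min(1.0, cfg.alloc_5plus_first4_prob[arm_idx] / p_start))
    na_eop = crossover & (rng.random(n) < cfg.nonalloc_eop_given_crossover)
    na_5plus = crossover & (rng.random(n) < cfg.nonalloc_5plus_given_crossover)
    na_occ = crossover & (rng.random(n) < cfg.nonalloc_occ_given_crossover)

    tqd = rng.random(n) < cfg.tqd_set_prob[arm_idx]
    contacted = rng.random(n) < cfg.contacted_prob
    withdrew = rng.random(n) < cfg.withdrew_prob

    # --- assays ---------------------------------------------------------------
    saliva = rng.random(n) < cfg.saliva_return_prob
    red_saliva = rng.random(n) < cfg.reducer_saliva_prob
    co_read = rng.random(n) < cfg.co_reading_prob
    product_user = alloc_eop | na_eop
    cot_high = _lognormal(rng, *cfg.cotinine_smoker, n)
    cot_low = _lognormal(rng, *cfg.cotinine_abstinent, n)
    anab_high = _lognormal(rng, *cfg.anabasine_smoker, n)
    anab_low = _lognormal(rng, *cfg.anabasine_abstinent, n)
    co_high = _lognormal(rng, *cfg.co_smoker, n)
    co_low = _lognormal(rng, *cfg.co_abstinent, n)
    # cotinine reflects any nicotine source; anabasine and CO only tobacco smoke
    cotinine = np.where(smoking_now | product_user, cot_high, cot_low)
    anabasine = np.where(smoking_now, anab_high, anab_low)
    co = np.where(smoking_now, co_high, co_low)

    # --- birth outcomes -------------------------------------------------------
    twins = rng.random(n) < cfg.twin_prob
    abstinent_eop = self_abstinent & ~smoking_now
    p_pre = np.where(abstinent_eop, cfg.preterm_prob_abstinent,
                     cfg.preterm_prob_smoker)
    preterm_event = rng.random(n) < p_pre
    ga = np.where(
        preterm_event,
        np.clip(rng.normal(cfg.ga_preterm_mean, cfg.ga_preterm_sd, n), 24.0, 36.9),
        np.clip(rng.normal(cfg.ga_term_mean, cfg.ga_term_sd, n), 37.0, 42.0))
    bw_mean = np.where(abstinent_eop, cfg.bw_mean_abstinent, cfg.bw_mean_smoker)
    bw_draws = rng.normal(0.0, cfg.bw_sd, (n, 2))
    ga_missing = rng.random(n) < cfg.ga_missing_prob
    bw_missing = rng.random(n) < cfg.bw_missing_prob
    miscarriage = rng.random(n) < cfg.miscarriage_prob
    stillbirth = rng.random(n) < cfg.stillbirth_prob
    neo_death = rng.random((n, 2)) < cfg.neonatal_death_prob
    post_neo = rng.random((n, 2)) < cfg.post_neonatal_death_prob
    nicu = rng.random((n, 2)) < cfg.nicu_prob
    congenital = rng.random((n, 2)) < cfg.congenital_prob
    cesarean = rng.random(n) < cfg.cesarean_prob

    records: List[ParticipantRecord] = []
    for i in range(n):
        baseline = ParticipantBaseline(
            age_years=float(age[i]),
            gestation_weeks_at_entry=float(gestation[i]),
            cigarettes_per_day=int(cigs[i]),
            ftcd_score=int(ftcd[i]),
            cotinine_ng_ml=None if base_cot_missing[i] else float(base_cot[i]),
            lives_with_smoker=bool(lives[i]),
            education=(Education.PRIMARY_SECONDARY, Education.FURTHER,
                       Education.HIGHER)[edu_idx[i]],
            employed=bool(employed[i]),
        )

        # weekly self-report timeline
        if quit[i]:
            weekly = [WeeklyStatus.SMOKING if wk1_smoking_q[i] else WeeklyStatus.ABSTINENT,
                      WeeklyStatus.ABSTINENT, WeeklyStatus.ABSTINENT,
                      WeeklyStatus.ABSTINENT]
            lapse = int(lapses_q[i])
        elif pp_only[i]:
            weekly = [WeeklyStatus.SMOKING] * 3 + [
                WeeklyStatus.ABSTINENT if wk4_abst_pp[i] else WeeklyStatus.SMOKING]
            lapse = int(lapses_pp[i])
        else:
            weekly = [WeeklyStatus.SMOKING] * 3 + [
                WeeklyStatus.ABSTINENT if wk4_abst_sm[i] else WeeklyStatus.SMOKING]
            lapse = int(lapses_sm[i])
        weekly = [WeeklyStatus.MISSING if weekly_missing[i, min(w, 3)] else s
                  for w, s in enumerate(weekly)]

        # end-of-pregnancy self-report
        eop_cigs: Optional[int] = None
        if not ascertained[i]:
            eop = EopReport.MISSING
        elif quit[i]:
            eop = (EopReport.ABSTINENT_AT_DELIVERY_RELAPSED_SINCE if relapsed[i]
                   else EopReport.ABSTINENT_7DAY)
        elif pp_only[i]:
            eop = EopReport.ABSTINENT_7DAY
        else:
            eop = EopReport.SMOKING
            ratio = red_ratio[i] if reduce50[i] else nonred_ratio[i]
            eop_cigs = max(1, int(round(float(cigs[i]) * float(ratio))))

        asked_for_sample = bool(ascertained[i]) and (
            self_abstinent[i] or (eop is EopReport.SMOKING and reduce50[i]))
        if not asked_for_sample:
            sal = False
        elif self_abstinent[i]:
            sal = bool(saliva[i])
        else:
            sal = bool(red_saliva[i])
        co_here = bool(co_read[i]) and asked_for_sample
        assays = AssayPanel(
            saliva_returned=sal,
            cotinine_ng_ml=float(cotinine[i]) if sal else None,
            anabasine_ng_ml=float(anabasine[i]) if sal else None,
            co_ppm=float(co[i]) if co_here else None,
            nicotine_product_user_at_validation=bool(product_user[i]),
        )

        product = ProductUsePattern(
            allocated_5plus_days_first4wks=bool(alloc_5plus[i]),
            allocated_current_4wks=bool(alloc_4wk[i]),
            allocated_current_eop=bool(alloc_eop[i]),
            allocated_regular_study=bool(alloc_regular[i]),
            nonallocated_5plus_consecutive_days_first4wks=bool(na_5plus[i]),
            nonallocated_current_eop=bool(na_eop[i]),
            nonallocated_regular_1wk=bool(crossover[i]),
            nonallocated_occasional_3wks=bool(na_occ[i]),
        )

        delivery: Optional[DeliveryRecord] = None
        if not withdrew[i]:
            n_inf = 2 if twins[i] else 1
            infants = []
            for j in range(n_inf):
                lost = bool(miscarriage[i] or stillbirth[i])
                bw = None
                ga_j = None
                if not lost:
                    if not ga_missing[i]:
                        ga_j = float(ga[i])
                    if not bw_missing[i]:
                        bw = max(350.0, float(
                            bw_mean[i] + bw_draws[i, j]
                            + cfg.bw_ga_slope * (ga[i] - 39.0)
                            - (cfg.twin_bw_deficit if n_inf == 2 else 0.0)))
                infants.append(InfantOutcome.from_measurements(
                    birthweight_g=bw,
                    gestational_age_weeks=ga_j,
                    miscarriage=bool(miscarriage[i]),
                    stillbirth=bool(stillbirth[i] and not miscarriage[i]),
                    neonatal_death=bool(neo_death[i, j] and not lost),
                    post_neonatal_death=bool(post_neo[i, j] and not lost
                                             and not neo_death[i, j]),
                    nicu_admission=bool(nicu[i, j] and not lost),
                    congenital_abnormality=bool(congenital[i, j]),
                    cesarean=bool(cesarean[i] and not lost),
                ))
            delivery = DeliveryRecord(infants=tuple(infants))

        records.append(ParticipantRecord(
            id=f"{arm.value}-{i + 1:04d}",
            arm=arm,
            baseline=baseline,
            tqd_set=bool(tqd[i]),
            contacted_ever=bool(contacted[i]),
            started_allocated_product=bool(started[i]),
            weekly_self_report=tuple(weekly),  # type: ignore[arg-type]
            lapse_count=lapse,
            eop_self_report=eop,
            eop_cigarettes_per_day=eop_cigs,
            product_use=product,
            assays=assays,
            withdrew_before_delivery=bool(withdrew[i]),
            delivery=delivery,
        ))
    return records


def generate_cohort(config: SimulationConfig,
                    seed: Optional[int] = None) -> List[ParticipantRecord]:
    """Generate one cohort; deterministic given (config, seed).

    ``seed`` overrides ``config.seed`` when given.  One root seed sequence is
    spawned into a fixed child stream per arm, so the draws for one arm are
    independent of the other arm's size and of evaluation order.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    children = root.spawn(2)
    records: List[ParticipantRecord] = []
    for arm_idx, arm in enumerate((Arm.ECIG, Arm.NRT)):
        rng = np.random.default_rng(children[arm_idx])
        records.extend(_simulate_arm(arm, arm_idx, config.n_per_arm[arm_idx],
                                     config, rng))
    return records


# ---------------------------------------------------------------------------
# Contamination worked-example cohorts
# ---------------------------------------------------------------------------

def _round_half_up_int(x: float) -> int:
    return int(math.floor(x + 0.5))


def worked_example_counts(n: int, pA: float, pB: float, fA: float, fB: float
                          ) -> dict:
    """Expected-value bookkeeping of the crossover illustration.

    Failures on the allocated product switch with the given per-arm fractions
    and succeed at the *other* product's true quit rate; expected counts are
    rounded half-up to integers, reproducing the illustration's arithmetic.
    """
    qA = _round_half_up_int(n * pA)
    qB = _round_half_up_int(n * pB)
    swA = _round_half_up_int(fA * (n - qA))
    swB = _round_half_up_int(fB * (n - qB))
    rescA = _round_half_up_int(pB * swA)   # arm-A switchers succeed at B's rate
    rescB = _round_half_up_int(pA * swB)
    return {"n": n,
            "quit_allocated": (qA, qB),
            "switchers": (swA, swB),
            "abstinent_switchers": (rescA, rescB),
            "quit_total": (qA + rescA, qB + rescB)}


def generate_worked_example_cohort(n: int, pA: float, pB: float,
                                   fA: float, fB: float,
                                   seed: Optional[int] = None
                                   ) -> List[ParticipantRecord]:
    """Cohort realizing the crossover illustration.

    Without a seed, expected counts are rounded deterministically so the
    cohort reproduces the illustration's arithmetic exactly; with a seed,
    each participant's quit / switch / rescue status is drawn stochastically.
    Records are fully ascertained and biochemically consistent with their
    smoking status, so any abstinence definition recovers the intended call.
    """
    for p in (pA, pB, fA, fB):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"invalid probability {p}")
    statuses = {}
    if seed is None:
        counts = worked_example_counts(n, pA, pB, fA, fB)
        for arm_i, arm in enumerate((Arm.ECIG, Arm.NRT)):
            q, sw, resc = (counts["quit_allocated"][arm_i],
                           counts["switchers"][arm_i],
                           counts["abstinent_switchers"][arm_i])
            # quitters, abstinent switchers, smoking switchers, plain failures
            status = (["quit"] * q + ["abst_switch"] * resc
                      + ["smoke_switch"] * (sw - resc)
                      + ["fail"] * (n - q - sw))
            statuses[arm] = status
    else:
        rng = np.random.default_rng(seed)
        for arm, p_own, p_other, f in ((Arm.ECIG, pA, pB, fA),
                                       (Arm.NRT, pB, pA, fB)):
            quit = rng.random(n) < p_own
            switch = (~quit) & (rng.random(n) < f)
            resc = switch & (rng.random(n) < p_other)
            status = np.where(quit, "quit",
                              np.where(resc, "abst_switch",
                                       np.where(switch, "smoke_switch", "fail")))
            statuses[arm] = list(status)

    records: List[ParticipantRecord] = []
    for arm in (Arm.ECIG, Arm.NRT):
        for i, status in enumerate(statuses[arm]):
            abstinent = status in ("quit", "abst_switch")
            switched = status in ("abst_switch", "smoke_switch")
            baseline = ParticipantBaseline(
                age_years=27.0, gestation_weeks_at_entry=16.0,
                cigarettes_per_day=10, ftcd_score=4, cotinine_ng_ml=115.0,
                lives_with_smoker=True, education=Education.FURTHER,
                employed=True)
            weekly = ((WeeklyStatus.ABSTINENT,) * 4 if abstinent
                      else (WeeklyStatus.SMOKING,) * 4)
            records.append(ParticipantRecord(
                id=f"{arm.value}-WE-{i + 1:04d}",
                arm=arm,
                baseline=baseline,
                tqd_set=True,
                contacted_ever=True,
                started_allocated_product=True,
                weekly_self_report=weekly,
                lapse_count=0,
                eop_self_report=(EopReport.ABSTINENT_7DAY if abstinent
                                 else EopReport.SMOKING),
                eop_cigarettes_per_day=None if abstinent else 10,
                product_use=ProductUsePattern(
                    allocated_regular_study=True,
                    nonallocated_regular_1wk=switched),
                assays=AssayPanel(
                    saliva_returned=True,
                    cotinine_ng_ml=1.0 if abstinent else 200.0,
                    anabasine_ng_ml=0.1 if abstinent else 3.0,
                    co_ppm=None,
                    nicotine_product_user_at_validation=False),
            ))
    return records
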