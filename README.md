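# nestcam

Estimating seabird breeding success from remote time-lapse camera networks.

Fixed cameras photographing penguin colonies every hour yield, after
annotation, a time series of chick counts per nest — but a chick not seen
in an image is not necessarily dead: parents brood chicks out of view, rain
blurs the lens, nests occlude each other. `nestcam` separates true nest
fate from imperfect observation with a hierarchical Bayesian state-space
model adapted from capture–recapture methodology, where nest locations play
the role of marks. It is aimed at quantitative ecologists running
camera-based monitoring of colonial, fixed-nest breeders (built around the
gentoo penguin's two-egg clutch) who want colony-level breeding success
with honest uncertainty, the within-season timing of nest failure, and
regressions of breeding success on environmental and anthropogenic drivers.

## The model

For nest *i* in site/year *(j,k)* over a 60-day season anchored at the
extrapolated lay date (crèche date − 60 days):

```
z_1 = 2,   z_t | z_{t-1} ~ Binomial(z_{t-1}, φ_jk)          latent chicks alive
y_t | z_t ~ Binomial(z_t, p_{t,i})                          observed count
logit(φ_jk)   = μφ_jk,          μφ_jk ~ N(θ_φ, σ_μφ)
logit(p_{t,i}) = μ_p + ν_i + β_jk · x_t,   x_t ∈ [0, 1]
```

Daily survival φ is constant within a site/year; detection rises
logistically over the season as chicks grow, with nest-level offsets.
The discrete states are marginalized exactly by a three-state forward
recursion and sampled with an adaptive Metropolis-within-Gibbs scheme;
latent trajectories are recovered by backward sampling. Derived
quantities: the colony total Z_t per day, and breeding success
BS = Z_60 / n_nests (chicks per pair, 0–2). Downstream, mortality rates in
the egg (days 1–30), young-chick (31–45) and old-chick (46–60) phases are
compared with a Friedman rank test, and breeding success is regressed on
precipitation-event counts, buffer-weighted krill catch (log tonnes within
150 km), and tourist visits, in errors-in-variables regressions that treat
each BS estimate as observed with its known posterior sd. A synthetic-data
module generates studies with known parameters for every stage, so the
whole pipeline is testable without field data. See `docs/methods.md` for
assumptions, priors and numerical choices.

## Worked example

```python
import nestcam as nc
from nestcam.phases import phase_rate_table

cfg = nc.SimulationConfig(n_sites=3, n_years_per_site=1, n_nests=20, rng_seed=1)
sims = [nc.simulate_site_year(cfg, i) for i in range(3)]
post = nc.fit_survival_model([s.to_observation_series() for s in sims])

print(f"max Rhat {post.max_rhat:.3f}, min ESS/chain {post.min_ess/4:.0f}")
rates = []
for g, sim in enumerate(sims):
    Z = nc.derive_total_chicks(post, group=g, rng_seed=0)
    bs = nc.breeding_success(post, group=g, rng_seed=0)
    rates.append(nc.phase_mortality(Z.mean(axis=0),
                                    site_id=sim.site_id, year_id=sim.year_id))
    print(f"{sim.site_id}/{sim.year_id}: BS {bs.mean:.2f} +/- {bs.sd:.2f} "
          f"(truth {sim.true_breeding_success:.2f})")
tab = phase_rate_table(rates)
fr = nc.friedman_test(tab[["egg", "young_chick", "old_chick"]].to_numpy())
print(f"Friedman Q = {fr.statistic:.2f} (df {fr.df}), p = {fr.p_value:.3f}")
```

prints (about 2 minutes on one core):

```
max Rhat 1.007, min ESS/chain 148
site01/2013-14: BS 1.55 +/- 0.01 (truth 1.50)
site02/2013-14: BS 1.54 +/- 0.04 (truth 1.55)
site03/2013-14: BS 1.12 +/- 0.03 (truth 1.10)
Friedman Q = 0.67 (df 2), p = 0.717
```

Each `BS` line is a colony's posterior-mean chicks per pair at crèche with
its posterior sd, against the simulated truth; the fit converged (Rhat
well below 1.1, effective sample sizes above 100 per chain). With only
three simulated site/years the Friedman test has no power to resolve phase
differences — at study scale (28 site/years) it separates egg-stage from
chick-stage mortality.

The same pipeline runs from the shell over CSV inputs (nest annotations,
chick detections, site metadata, covariate tables):

```
nestcam run --config study.yaml --seed 1 --out results/
nestcam simulate --seed 4 --out demo/          # synthetic study
nestcam fit --series demo/observation_series.csv --out demo/
```

Every run writes a manifest with SHA-256 checksums; identical config and
seed reproduce identical outputs.

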