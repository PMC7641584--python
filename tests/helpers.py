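"""Independent oracles and cohort builders shared by the test suite."""

import numpy as np

from poselab import synth
from poselab.design import CHOICE_DIRECTIONS, SurfacePose
from poselab.spikes import SDFKernel, spike_density_matrix


def grid_search_mle(counts, mu_step=0.25, kappa_step=0.02):
    """Dense grid-search MLE of the discretized von Mises error model.

    Independent of the package's optimizer: direct evaluation of the
    multinomial log likelihood over a (mu, kappa) lattice.
    """
    mus = np.arange(-180.0, 180.0, mu_step)
    kappas = np.arange(kappa_step, 18.0 + 1e-9, kappa_step)
    bins = np.array([-135.0, -90.0, -45.0, 0.0, 45.0, 90.0, 135.0, 180.0])
    c = np.cos(np.deg2rad(bins[None, :] - mus[:, None]))        # (mu, 8)
    best = (-np.inf, None, None)
    for k in kappas:
        p = np.exp(k * (c - 1.0))
        p /= p.sum(axis=1, keepdims=True)
        ll = (counts * np.log(p)).sum(axis=1)
        i = int(np.argmax(ll))
        if ll[i] > best[0]:
            best = (float(ll[i]), float(mus[i]), float(k))
    return best           # (loglik, mu, kappa)


def als_oracle(M, n_iter=600, tol=1e-12, seed=0):
    """Alternating-least-squares fit of DC + g h f^T (no SVD): closed-form
    rank-1 power steps alternated with the mean-residual DC update."""
    rng = np.random.default_rng(seed)
    h = rng.normal(size=M.shape[0])
    f = rng.normal(size=M.shape[1])
    dc = float(M.mean())
    prev = np.inf
    for _ in range(n_iter):
        R = M - dc
        h = R @ f / (f @ f)
        f = R.T @ h / (h @ h)
        dc = float((M - np.outer(h, f)).mean())
        obj = float(np.linalg.norm(M - dc - np.outer(h, f)))
        if abs(prev - obj) < tol:
            break
        prev = obj
    if dc < 0:                      # implementation constrains DC >= 0
        dc = 0.0
        R = M
        for _ in range(n_iter):
            h = R @ f / (f @ f)
            f = R.T @ h / (h @ h)
        obj = float(np.linalg.norm(M - np.outer(h, f)))
    return obj, dc


def random_rank1_matrix(rng, n_o=33, n_d=4):
    """Rank-1-plus-offset matrix with additive noise, the generic input for
    the separable-fit oracle comparison."""
    dc = rng.uniform(0, 10)
    g = rng.uniform(5, 40)
    h = np.abs(rng.normal(1, 0.5, n_o))
    f = np.abs(rng.normal(1, 0.4, n_d))
    noise = rng.normal(0, rng.uniform(0.5, 4.0), (n_o, n_d))
    return dc + g * np.outer(h / np.linalg.norm(h),
                             f / np.linalg.norm(f)) + noise


def choice_trace_cohort(n_neurons, n_trials, choice_kappa, seed,
                        choice_onset=200.0):
    """Per-neuron per-choice mean z-scored SDF traces from fully simulated
    frontoparallel spike trains — the input of the choice-onset estimator."""
    rng = np.random.default_rng(seed)
    cohort = synth.make_neuron_cohort(n_neurons, seed=seed,
                                      choice_fraction=1.0,
                                      choice_onset=choice_onset,
                                      choice_kappa=choice_kappa)
    kernel = SDFKernel()
    traces = []
    for spec in cohort:
        dists = np.tile([37.0, 57.0, 97.0, 137.0], n_trials // 4)
        choices = rng.choice(CHOICE_DIRECTIONS, size=n_trials)
        trains = [synth.simulate_neuron_trial(
            spec, SurfacePose(float("nan"), 0.0, d), c, seed=rng)
            for d, c in zip(dists, choices)]
        sdf = spike_density_matrix(trains, 0.0, 1000.0, kernel)
        zs = np.zeros_like(sdf)
        for d in np.unique(dists):
            m = dists == d
            mu, sd = sdf[m].mean(), sdf[m].std()
            zs[m] = (sdf[m] - mu) / (sd if sd > 0 else 1.0)
        ctr = np.zeros((8, sdf.shape[1]))
        for k, c in enumerate(CHOICE_DIRECTIONS):
            m = choices == c
            if m.any():
                ctr[k] = zs[m].mean(axis=0)
        traces.append(ctr)
    return np.array(traces)


def saccade_ramp_trials(n_trials, seed, direction=90.0):
    """Preferred-direction saccade trials: saccade-aligned SDF traces and
    the drawn latencies."""
    rng = np.random.default_rng(seed)
    spec = synth.NeuronSpec(saccade_kappa=3.0, saccade_pref=direction)
    kernel = SDFKernel()
    sdfs, lats = [], []
    for _ in range(n_trials):
        out = synth.simulate_saccade_trial(spec, direction, seed=rng)
        aligned = out["spikes"] - out["latency_ms"]
        sdfs.append(spike_density_matrix([aligned], -300.0, 100.0, kernel)[0])
        lats.append(out["latency_ms"])
    return np.array(sdfs), np.array(lats), spec
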