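"""Trial-wise Bayesian surprise over oddball cue sequences.

Surprise for an event on trial *i* is quantified as the Kullback-Leibler
divergence between the posterior and prior probability of that event
category::

    surprise_i = log2( p_event(1..i) / p_event(1..i-1) )

where the prior is the proportion of category events among all trials
before trial *i* and the posterior is the proportion including trial *i*.
The ratio is bounded in [1, 2], so surprise is bounded in [0, 1]; the
first occurrence of a category (prior = 0) is assigned the maximum
surprise of 1.

Three model variants are provided:

* ``separate`` — one counter per sensory modality (an unexpected sound
  does not reduce surprise for a later unexpected visual event), counts
  referenced to all elapsed trials.
* ``common`` — a single counter over unexpected events of any modality.
* ``separate_exclusive`` — per-modality counters referenced to the
  reduced trial base that excludes the *other* modality's unexpected
  trials, encoding the mutual exclusivity of the design (a trial can be
  unexpected in at most one modality).
"""

from __future__ import annotations

import math
from typing import Iterable

import pandas as pd

MODELS = ("separate", "common", "separate_exclusive")

_UNEXPECTED = {"unexpected_auditory": "auditory", "unexpected_visual": "visual"}


def surprise_value(k_prior: int, n_prior: int) -> float:
    """Bayesian surprise for an event with `k_prior` same-category events
    among `n_prior` prior trials.

    Returns ``log2(((k+1)/(n+1)) / (k/n))``; by convention 1.0 (maximum
    surprise) when ``k_prior == 0``, where the prior is zero.
    """
    if k_prior < 0 or n_prior < 0:
        raise ValueError("counts must be non-negative")
    if k_prior > n_prior:
        raise ValueError("k_prior cannot exceed n_prior")
    if k_prior == 0:
        return 1.0
    prior = k_prior / n_prior
    posterior = (k_prior + 1) / (n_prior + 1)
    return math.log2(posterior / prior)


def _prior_posterior(k_prior: int, n_prior: int) -> tuple[float, float]:
    prior = k_prior / n_prior if n_prior > 0 else 0.0
    posterior = (k_prior + 1) / (n_prior + 1)
    return prior, posterior


def compute_surprise(
    trials: Iterable,
    model: str = "separate",
    include_standards: bool = False,
    subject_id: str | None = None,
) -> pd.DataFrame:
    """Score a cue sequence trial-by-trial under one surprise model.

    Parameters
    ----------
    trials
        Ordered oddball trials; each needs ``index`` and ``cue_type``
        attributes (or mapping keys).
    model
        One of ``separate``, ``common``, ``separate_exclusive``.
    include_standards
        If True, standard-cue trials are additionally scored as events of
        their own "standard" category; by default only unexpected-cue
        trials are scored.

    Returns
    -------
    DataFrame with columns trial_index, modality, prior_p, posterior_p,
    surprise, model_id, include_standards — one row per scored trial.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    trials = list(trials)
    if not trials:
        raise ValueError("empty trial list")

    def field(t, name):
        return t[name] if isinstance(t, dict) else getattr(t, name)

    rows = []
    # event counters
    k_aud = k_vis = k_any = k_std = 0
    for n_prior, t in enumerate(trials):
        cue = field(t, "cue_type")
        modality = _UNEXPECTED.get(cue)
        scored = modality is not None or include_standards
        if not scored:
            pass
        else:
            if modality is None:
                # standard-cue trial scored as its own category; the
                # exclusive variant reduces nothing for standards.
                k, base = k_std, n_prior
                label = "standard"
            elif model == "common":
                k, base = k_any, n_prior
                label = modality
            elif model == "separate":
                k = k_aud if modality == "auditory" else k_vis
                base = n_prior
                label = modality
            else:  # separate_exclusive: remove the other modality's
                # unexpected trials from the sample space
                if modality == "auditory":
                    k, base = k_aud, n_prior - k_vis
                else:
                    k, base = k_vis, n_prior - k_aud
                label = modality
            prior_p, posterior_p = _prior_posterior(k, base)
            surprise = surprise_value(k, base)
            rows.append(
                {
                    "trial_index": field(t, "index"),
                    "modality": label,
                    "prior_p": prior_p,
                    "posterior_p": posterior_p,
                    "surprise": surprise,
                    "model_id": model,
                    "include_standards": include_standards,
                }
            )
        # update counters after scoring
        if modality == "auditory":
            k_aud += 1
            k_any += 1
        elif modality == "visual":
            k_vis += 1
            k_any += 1
        else:
            k_std += 1

    columns = [
        "trial_index", "modality", "prior_p", "posterior_p",
        "surprise", "model_id", "include_standards",
    ]
    out = pd.DataFrame(rows, columns=columns)
    if subject_id is not None:
        out.insert(0, "subject_id", subject_id)
    return out


def unexpected_only(series: pd.DataFrame) -> pd.DataFrame:
    """Restrict a surprise series to unexpected-cue rows."""
    return series[series["modality"] != "standard"].reset_index(drop=True)
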