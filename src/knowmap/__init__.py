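"""knowmap: conceptual knowledge maps from short multiple-choice quizzes.

The package embeds lecture transcripts and quiz questions in a shared topic
space (LDA over ramping sliding windows of transcript text), estimates
per-concept knowledge from graded quiz responses as a correlation-weighted
proportion correct, validates those estimates with logistic mixed models and
parametric-bootstrap likelihood-ratio tests, quantifies how smoothly knowledge
falls off with embedding distance, and renders 2D knowledge / learning maps.

Subpackage layout mirrors the pipeline:

- :mod:`knowmap.ingest`      -- transcript / question-pool / response readers
- :mod:`knowmap.corpus`      -- sliding-window corpus and text preprocessing
- :mod:`knowmap.topics`      -- LDA fitting, k selection, 1 Hz trajectories
- :mod:`knowmap.correspond`  -- question-to-lecture-moment matching
- :mod:`knowmap.knowledge`   -- knowledge traces and held-out estimates
- :mod:`knowmap.mixedmodel`  -- logistic GLMM, bootstrap CIs and LRTs
- :mod:`knowmap.smoothness`  -- concentric-sphere curves, divergence distances
- :mod:`knowmap.maps`        -- 2D projections, RBF knowledge / learning maps
- :mod:`knowmap.synthetic`   -- simulated lectures, questions and learners
- :mod:`knowmap.cli`         -- command-line pipeline orchestration
"""

__version__ = "0.1.0"


class KnowmapWarning(UserWarning):
    """Base warning for degenerate-but-recoverable numerical situations."""
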