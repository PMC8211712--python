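"""karstrad: diagnosing adaptive radiation on time-calibrated phylogenies.

Tooling for the standard macroevolutionary battery applied to a dated
phylogeny: lineage-through-time and gamma analysis, birth-death /
diversity-dependent model selection, stochastic character mapping and
changes-through-time curves for discrete habitats, disparity-through-time
and rank envelope tests for continuous traits, multivariate trait-evolution
model selection with a fixed-time mode shift, SURFACE-style convergent-peak
detection, and Brownian ancestral-range reconstruction on the sphere.
"""

from .tree import TimeTree, TreeError, read_tree, branching_times, lineages_at_time, extract_clade, validate_clades

__version__ = "0.1.0"

__all__ = [
    "TimeTree",
    "TreeError",
    "read_tree",
    "branching_times",
    "lineages_at_time",
    "extract_clade",
    "validate_clades",
    "gamma_statistic",
    "gamma_test",
    "DiversificationModel",
    "MkModel",
    "TraitEvolutionModel",
    "SurfaceModel",
    "GeoBrownianModel",
    "dtt_test",
    "make_reference_dataset",
]


def __getattr__(name):
    # lazy imports keep `import karstrad` light
    if name in ("gamma_statistic", "gamma_test", "DiversificationModel"):
        from . import diversification

        return getattr(diversification, name)
    if name == "MkModel":
        from .mk import MkModel

        return MkModel
    if name == "TraitEvolutionModel":
        from .traitmodels import TraitEvolutionModel

        return TraitEvolutionModel
    if name == "SurfaceModel":
        from .surface import SurfaceModel

        return SurfaceModel
    if name == "GeoBrownianModel":
        from .geo import GeoBrownianModel

        return GeoBrownianModel
    if name == "dtt_test":
        from .disparity import dtt_test

        return dtt_test
    if name == "make_reference_dataset":
        from .simulate import make_reference_dataset

        return make_reference_dataset
    raise AttributeError(name)
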