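"""Exception hierarchy shared across the package."""


class CondentropyError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CondentropyError):
    """A tabular input violates the expected dialect or an invariant."""


class UnmappedSampleError(CondentropyError):
    """Count-matrix samples missing from the condition table."""

    def __init__(self, samples):
        self.samples = sorted(samples)
        super().__init__(
            "samples absent from condition table: " + ", ".join(self.samples)
        )


class EmptyGeneSetError(CondentropyError):
    """A gene-set file yielded no usable identifiers."""


class EmptyBenchmarkError(CondentropyError):
    """No gene in the benchmark set has a defined specificity score."""


class DegenerateDistributionError(CondentropyError):
    """Scores have zero variance; a density estimate is undefined."""
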