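"""Exception hierarchy shared across the package."""


class CausalMRError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CausalMRError):
    """Invalid column mapping, study configuration, or parameter value."""


class EmptyTableError(CausalMRError):
    """An input table contained no usable rows."""


class EmptyInstrumentError(CausalMRError):
    """No variant passed the instrument-selection threshold for a trait."""


class HarmonizationEmptyError(CausalMRError):
    """No variant survived harmonization or an exclusion filter."""


class MissingFromPanelError(CausalMRError):
    """Variants absent from the LD panel with no usable proxy."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"SNPs absent from LD panel: {', '.join(self.missing)}")


class InsufficientInstrumentsError(CausalMRError):
    """Too few instruments for the requested estimator or diagnostic."""


class DegenerateInstrumentError(CausalMRError):
    """An instrument with zero exposure effect cannot yield a Wald ratio."""


class CollinearExposuresError(CausalMRError):
    """Multivariable design matrix is rank deficient."""
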