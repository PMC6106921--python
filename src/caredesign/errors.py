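"""Exception types shared across the package."""


class CaredesignError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CaredesignError):
    """An input refers to something undeclared (parameter id, staff grade, rule)."""


class ModelSpecificationError(CaredesignError):
    """The model itself is ill-posed (e.g. a non-positive impact-column sum)."""


class BundleValidationError(CaredesignError):
    """A bundle failed cross-validation; carries every violation, not just the first."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "\n".join(f"  - {v}" for v in self.violations)
        super().__init__(f"{len(self.violations)} validation failure(s):\n{lines}")
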