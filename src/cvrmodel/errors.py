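"""Exception types shared across the model."""


class ValidationError(ValueError):
    """An input violates a model precondition (bad profile, malformed scenario)."""


class DomainError(ValueError):
    """Inputs are formally valid but outside the domain the model was fitted on."""
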