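a
an
and
are
as
at
be
been
by
for
from
had
has
have
he
her
his
in
is
it
its
no
not
of
on
or
she
that
the
their
there
these
they
this
to
was
were
will
with
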