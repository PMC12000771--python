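# Default stopword list: the common English function words enumerated in the
# extraction workflow plus a standard small English set. Override per run.
a
an
and
are
as
at
be
by
for
from
has
he
in
is
it
its
of
on
that
the
to
was
were
will
with
i
me
my
we
our
you
your
she
her
they
them
their
this
these
those
am
been
being
have
had
having
do
does
did
but
if
or
because
until
while
about
against
between
into
through
during
before
after
above
below
up
down
out
off
over
under
again
then
once
here
there
when
where
why
how
all
any
both
each
few
more
most
other
some
such
no
nor
not
only
own
same
so
than
too
very
can
just
now
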