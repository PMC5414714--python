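/root/pkg/src/tumortyperprofiles.pypatterns.pypipeline.pyannotation.py__init__.pysynthetic.py   dags.py��!��0Ǭ3�3���         votes.py�׆,�2 �3���         boost.pyZ����3���                                         �   q����׆,�2 �3���         cli.py��8y��M��3���         �   &���V�mǶ�;�3���         �   �����k @3��@�3���         �   �����!��0Ǭ3�3���         �   ������2��3���         �   x����׆,�2 �3���         o)A.7:�^]#o)A.7:�^]#��������� �    �������
      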